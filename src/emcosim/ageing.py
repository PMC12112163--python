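"""Young / Aged metabolic perturbation protocols.

Ageing is modelled purely on the metabolic side as multiplicative changes to
parameters and initial concentrations: electron-transport-chain (ETC)
dysfunction, reduced arterial and intracellular glucose, downregulated
beta-hydroxybutyrate, elevated intracellular lactate, depletion of the total
NAD pool, reduced cytosol-to-mitochondria NADH shuttling, and downregulated
glutamate drive of astrocytic glycolysis.  Electrophysiology and morphology
are untouched and the stimulus is kept identical between conditions, so any
Young/Aged difference in spiking is mediated by energy availability alone.

The default Aged magnitudes are this package's choices (the direction of
each change is the constraint; see docs/methods.md); all factors are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Tuple

from .metabolism import MetabolicParams, MetabolicState

__all__ = ["AgeingProfile", "YOUNG", "AGED_DEFAULT", "apply_profile",
           "age_population"]


@dataclass(frozen=True)
class AgeingProfile:
    """Multiplicative perturbation of the NGV metabolic model.

    All factors are positive scalars; 1.0 everywhere is the Young
    (identity) profile.  ``lac_n_initial_factor`` >= 1 (lactate accumulates
    with age); the remaining defaults are <= 1 (capacities decline).
    """

    name: str = "young"
    etc_efficiency_factor: float = 1.0
    glc_art_factor: float = 1.0
    glc_intracellular_factor: float = 1.0
    bhb_factor: float = 1.0
    lac_n_initial_factor: float = 1.0
    nad_tot_factor: float = 1.0
    nadh_shuttle_factor: float = 1.0
    glutamate_drive_factor: float = 1.0

    def __post_init__(self) -> None:
        for f_ in fields(self):
            if f_.name == "name":
                continue
            v = getattr(self, f_.name)
            if v <= 0:
                raise ValueError(f"{f_.name} must be > 0, got {v}")
        if self.lac_n_initial_factor < 1.0:
            raise ValueError("lac_n_initial_factor must be >= 1 (lactate rises)")

    def is_identity(self) -> bool:
        return all(getattr(self, f_.name) == 1.0 for f_ in fields(self)
                   if f_.name != "name")


YOUNG = AgeingProfile(name="young")

#: default Aged protocol; directions fixed by the ageing literature,
#: magnitudes are configurable model choices
AGED_DEFAULT = AgeingProfile(
    name="aged",
    etc_efficiency_factor=0.85,
    glc_art_factor=0.80,
    glc_intracellular_factor=0.80,
    bhb_factor=0.70,
    lac_n_initial_factor=1.20,
    nad_tot_factor=0.70,
    nadh_shuttle_factor=0.75,
    glutamate_drive_factor=0.80,
)


def apply_profile(p: MetabolicParams, s0: MetabolicState, prof: AgeingProfile
                  ) -> Tuple[MetabolicParams, MetabolicState]:
    """Apply an ageing profile to metabolic parameters and initial state.

    Returns new objects; inputs are not modified.  The NAD-pool factor
    scales both the total pool and the initial NADH content so the redox
    ratio is preserved at t=0.
    """
    p2 = replace(
        p,
        etc_efficiency=p.etc_efficiency * prof.etc_efficiency_factor,
        glc_art=p.glc_art * prof.glc_art_factor,
        bhb_art=p.bhb_art * prof.bhb_factor,
        nad_tot_n=p.nad_tot_n * prof.nad_tot_factor,
        v_shuttle=p.v_shuttle * prof.nadh_shuttle_factor,
        glu_drive=p.glu_drive * prof.glutamate_drive_factor,
    )
    s2 = replace(
        s0,
        glc_n=s0.glc_n * prof.glc_intracellular_factor,
        glc_a=s0.glc_a * prof.glc_intracellular_factor,
        glc_c=s0.glc_c * prof.glc_art_factor,
        lac_n=s0.lac_n * prof.lac_n_initial_factor,
        bhb_c=s0.bhb_c * prof.bhb_factor,
        nadh_n=s0.nadh_n * prof.nad_tot_factor,
        nadh_m=s0.nadh_m * prof.nad_tot_factor,
    )
    return p2, s2


def age_population(population, prof: AgeingProfile):
    """Apply a profile to every neuron of a built population.

    Only the metabolic side changes; electrophysiology, stimulus and RNG
    streams are untouched, preserving the paired Young/Aged design.
    """
    out = []
    for nr in population:
        p2, s2 = apply_profile(nr.met_params, nr.met_rest, prof)
        out.append(replace(nr, met_params=p2, met_rest=s2))
    return out
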