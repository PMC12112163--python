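"""Reduced neuro-glia-vasculature (NGV) metabolic ODE system.

One NGV unit supplies ATP to one neuron.  The model is a deliberately small
surrogate of the full compartmental metabolic pathway inventory: ~15 state
variables and ~12 lumped saturable fluxes spanning a neuronal compartment
(glucose, pyruvate, lactate, cytosolic and mitochondrial NADH, ATP,
phosphocreatine, oxygen), an astrocytic compartment (glucose, lactate, ATP;
the astrocyte-neuron lactate shuttle), and a capillary compartment exchanging
glucose, lactate, oxygen and beta-hydroxybutyrate with a fixed arterial
boundary at a rate set by the (fixed) blood flow.

Key regulatory features preserved from detailed models:

* glycolysis yields 2 ATP + 2 pyruvate + 2 NADH per glucose and is activated
  by ADP and limited by cytosolic NAD+;
* oxidative phosphorylation is saturable in pyruvate, O2 and ADP
  (respiratory control), scaled by an electron-transport-chain efficiency
  factor and a layer-specific mitochondrial density multiplier;
* an NADH shuttle moves reducing equivalents from cytosol to mitochondria
  where they fuel additional oxidative ATP production;
* a fast reversible creatine-kinase reaction buffers ATP transients;
* a housekeeping ATPase provides the non-signalling baseline drain.

The ADP feedback (ADP = A - ATP within this module) makes ATP production
track consumption: when the synchronised ATP drops, production rises until
supply and demand balance, which is the physics the co-simulation exercises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "MetabolicState",
    "MetabolicParams",
    "MetSegmentResult",
    "MetabolicModelError",
    "CalibrationError",
    "metabolic_rhs",
    "metabolic_fluxes",
    "resting_steady_state",
    "run_metabolism_segment",
    "scale_mitochondria",
    "STATE_NAMES",
]

STATE_NAMES = (
    "glc_n", "pyr_n", "lac_n", "nadh_n", "nadh_m", "atp_n", "pcr_n", "o2_n",
    "glc_a", "lac_a", "atp_a",
    "glc_c", "lac_c", "o2_c", "bhb_c",
)

_I = {name: i for i, name in enumerate(STATE_NAMES)}


class MetabolicModelError(RuntimeError):
    """A flux evaluated to a non-finite value."""


class CalibrationError(RuntimeError):
    """No resting steady state found within the iteration budget."""


@dataclass
class MetabolicState:
    """Metabolite concentrations (mM) of one NGV unit.

    Suffixes: _n neuronal cytosol (``nadh_m`` mitochondrial), _a astrocyte,
    _c capillary.  ``atp_produced_cum`` accumulates gross neuronal ATP
    production (mM) since the start of the current segment chain.
    """

    glc_n: float = 3.50
    pyr_n: float = 0.057
    lac_n: float = 0.95
    nadh_n: float = 0.0008
    nadh_m: float = 0.003
    atp_n: float = 1.38
    pcr_n: float = 4.20
    o2_n: float = 2.69
    glc_a: float = 3.78
    lac_a: float = 1.17
    atp_a: float = 1.40
    glc_c: float = 4.5
    lac_c: float = 1.0
    o2_c: float = 7.0
    bhb_c: float = 0.3
    atp_produced_cum: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, y, atp_produced_cum: float = 0.0) -> "MetabolicState":
        kw = {n: float(y[i]) for i, n in enumerate(STATE_NAMES)}
        return cls(atp_produced_cum=atp_produced_cum, **kw)

    def validate(self, a_tot: Optional[float] = None,
                 nad_tot: Optional[float] = None) -> None:
        for n in STATE_NAMES:
            if getattr(self, n) < 0:
                raise ValueError(f"concentration {n} must be >= 0")
        if a_tot is not None and self.atp_n > a_tot + 1e-9:
            raise ValueError(f"atp_n={self.atp_n} exceeds adenine pool {a_tot}")
        if nad_tot is not None and self.nadh_n > nad_tot + 1e-9:
            raise ValueError(f"nadh_n={self.nadh_n} exceeds NAD pool {nad_tot}")


@dataclass(frozen=True)
class MetabolicParams:
    """Rate constants of the reduced NGV model (mM, ms units).

    ``v_gly_n`` is calibrated so that, at the default resting demand, the
    neuronal ATP steady state sits at 1.38 mM.
    """

    # glucose transport (capillary -> cytosol), symmetric carrier
    t_glc_n: float = 1e-5
    t_glc_a: float = 5e-6
    k_glc_t: float = 8.0
    # lumped glycolysis; v_gly_n calibrated for a 1.38 mM resting ATP
    v_gly_n: float = 9.407078079e-6
    v_gly_a: float = 3.0e-6
    k_gly: float = 0.5
    k_nad: float = 0.05
    k_adp_gly: float = 0.5
    # lactate dehydrogenase (neuron, reversible mass action)
    k_ldh_f: float = 2e-5
    k_ldh_r: float = 4.2e-7
    # monocarboxylate transport
    t_mct_an: float = 8e-6
    t_mct_cn: float = 5e-7
    k_mct: float = 2.0
    # oxygen transport
    t_o2: float = 4e-5
    k_o2_t: float = 1.0
    # oxidative phosphorylation (pyruvate route); near ADP-saturation
    # (weak respiratory-control gain) so capacity changes are felt, see docs
    v_ox: float = 8e-6
    k_pyr: float = 0.08
    k_o2_m: float = 0.02
    k_adp_ox: float = 0.02
    n_atp_ox: float = 13.0
    o2_per_pyr: float = 2.5
    # NADH shuttle + mitochondrial oxidation of shuttled NADH
    v_shuttle: float = 2e-5
    k_shuttle: float = 0.01
    nadh_m_cap: float = 0.3
    k_etc: float = 5e-4
    n_atp_shuttle: float = 2.5
    o2_per_shuttle: float = 0.5
    # beta-hydroxybutyrate oxidation
    v_bhb: float = 6.7e-7
    k_bhb: float = 0.15
    n_atp_bhb: float = 10.0
    o2_per_bhb: float = 4.0
    # creatine kinase buffer
    k_ck: float = 5e-4
    ck_keq_inv: float = 0.228
    pcr_tot: float = 5.0
    # housekeeping ATPases
    v_hk: float = 2e-5
    k_hk: float = 0.4
    v_hk_a: float = 5e-7
    # pools and modifiers
    a_tot: float = 1.44
    a_tot_a: float = 1.44
    nad_tot_n: float = 0.5
    etc_efficiency: float = 1.0
    mito_density_scale: float = 1.0
    glu_drive: float = 1.0
    # boundary / vascular
    glc_art: float = 4.5
    lac_art: float = 1.0
    o2_art: float = 7.0
    bhb_art: float = 0.3
    blood_flow: float = 0.0001  # ml/min (fixed; not dynamically modelled)
    blood_volume: float = 0.023  # ml
    vol_ratio: float = 1e-6  # neuron-tissue : capillary volume ratio
    # reference demand and solver settings
    demand_rest: float = 2e-5  # mM/ms
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, float) and f_.name not in ("rtol", "atol") and v < 0:
                raise ValueError(f"{f_.name} must be >= 0")
        if not (0.0 <= self.etc_efficiency <= 1.0):
            raise ValueError("etc_efficiency must lie in [0, 1]")

    @property
    def cap_refresh(self) -> float:
        """Capillary refresh rate (1/ms) = blood_flow / blood_volume."""
        return self.blood_flow / 60000.0 / self.blood_volume


@dataclass
class MetSegmentResult:
    final_state: MetabolicState
    atp_produced: float
    atp_sink: float  # housekeeping + net creatine-kinase uptake (mM)
    n_steps: int
    n_rhs_evals: int
    clamp_events: int = 0


def _mm(x: float, k: float) -> float:
    return x / (x + k) if x > 0.0 else 0.0


def metabolic_fluxes(y, p: MetabolicParams, demand: float) -> Dict[str, float]:
    """All lumped fluxes (mM/ms) at state vector ``y``.

    Raises :class:`MetabolicModelError` naming the first non-finite flux.
    """
    glc_n, pyr_n, lac_n, nadh_n, nadh_m, atp_n, pcr_n, o2_n = (
        y[_I["glc_n"]], y[_I["pyr_n"]], y[_I["lac_n"]], y[_I["nadh_n"]],
        y[_I["nadh_m"]], y[_I["atp_n"]], y[_I["pcr_n"]], y[_I["o2_n"]])
    glc_a, lac_a, atp_a = y[_I["glc_a"]], y[_I["lac_a"]], y[_I["atp_a"]]
    glc_c, lac_c, o2_c, bhb_c = (
        y[_I["glc_c"]], y[_I["lac_c"]], y[_I["o2_c"]], y[_I["bhb_c"]])

    adp = max(p.a_tot - atp_n, 0.0)
    adp_a = max(p.a_tot_a - atp_a, 0.0)
    nad_plus = max(p.nad_tot_n - nadh_n, 0.0)
    nadh_frac = min(nadh_n / p.nad_tot_n, 1.0) if nadh_n > 0 else 0.0
    nad_frac = nad_plus / p.nad_tot_n
    mito = p.etc_efficiency * p.mito_density_scale
    f_adp = _mm(adp, p.k_adp_ox)
    f_o2 = _mm(o2_n, p.k_o2_m)

    j = {
        "glc_transport_n": p.t_glc_n * (_mm(glc_c, p.k_glc_t) - _mm(glc_n, p.k_glc_t)),
        "glc_transport_a": p.t_glc_a * (_mm(glc_c, p.k_glc_t) - _mm(glc_a, p.k_glc_t)),
        "glycolysis_n": p.v_gly_n * _mm(glc_n, p.k_gly) * _mm(nad_plus, p.k_nad)
        * _mm(adp, p.k_adp_gly),
        "glycolysis_a": p.v_gly_a * p.glu_drive * _mm(glc_a, p.k_gly)
        * _mm(adp_a, p.k_adp_gly),
        "ldh_n": p.k_ldh_f * max(pyr_n, 0.0) * nadh_frac
        - p.k_ldh_r * max(lac_n, 0.0) * nad_frac,
        "mct_an": p.t_mct_an * (_mm(lac_a, p.k_mct) - _mm(lac_n, p.k_mct)),
        "mct_cn": p.t_mct_cn * (_mm(lac_c, p.k_mct) - _mm(lac_n, p.k_mct)),
        "o2_transport": p.t_o2 * (_mm(o2_c, p.k_o2_t) - _mm(o2_n, p.k_o2_t)),
        "oxphos": p.v_ox * mito * _mm(pyr_n, p.k_pyr) * f_o2 * f_adp,
        "nadh_shuttle": p.v_shuttle * _mm(nadh_n, p.k_shuttle)
        * max(1.0 - nadh_m / p.nadh_m_cap, 0.0),
        "etc_shuttle": p.k_etc * mito * max(nadh_m, 0.0) * f_o2,
        "bhb_oxidation": p.v_bhb * mito * _mm(bhb_c, p.k_bhb) * f_o2 * f_adp,
        "creatine_kinase": p.k_ck * (max(pcr_n, 0.0) * adp
                                     - p.ck_keq_inv * max(p.pcr_tot - pcr_n, 0.0) * atp_n),
        "housekeeping_n": p.v_hk * _mm(atp_n, p.k_hk),
        "housekeeping_a": p.v_hk_a * _mm(atp_a, p.k_hk),
        "demand": demand,
    }
    for name, val in j.items():
        if not math.isfinite(val):
            raise MetabolicModelError(f"non-finite flux '{name}'")
    return j


def _assemble(y, p: MetabolicParams, j: Dict[str, float]) -> np.ndarray:
    """State derivatives from the flux dictionary."""
    dy = np.zeros(len(STATE_NAMES))
    ck = j["creatine_kinase"]
    produced = (2.0 * j["glycolysis_n"] + p.n_atp_ox * j["oxphos"]
                + p.n_atp_shuttle * j["etc_shuttle"]
                + p.n_atp_bhb * j["bhb_oxidation"] + max(ck, 0.0))
    sink = j["housekeeping_n"] + max(-ck, 0.0)

    dy[_I["glc_n"]] = j["glc_transport_n"] - j["glycolysis_n"]
    dy[_I["pyr_n"]] = 2.0 * j["glycolysis_n"] - j["ldh_n"] - j["oxphos"]
    dy[_I["lac_n"]] = j["ldh_n"] + j["mct_an"] + j["mct_cn"]
    dy[_I["nadh_n"]] = 2.0 * j["glycolysis_n"] - j["ldh_n"] - j["nadh_shuttle"]
    dy[_I["nadh_m"]] = j["nadh_shuttle"] - j["etc_shuttle"]
    dy[_I["atp_n"]] = produced - sink - j["demand"]
    dy[_I["pcr_n"]] = -ck
    dy[_I["o2_n"]] = (j["o2_transport"] - p.o2_per_pyr * j["oxphos"]
                      - p.o2_per_shuttle * j["etc_shuttle"]
                      - p.o2_per_bhb * j["bhb_oxidation"])
    dy[_I["glc_a"]] = j["glc_transport_a"] - j["glycolysis_a"]
    dy[_I["lac_a"]] = 2.0 * j["glycolysis_a"] - j["mct_an"]
    dy[_I["atp_a"]] = 2.0 * j["glycolysis_a"] - j["housekeeping_a"]

    kf = p.cap_refresh
    vr = p.vol_ratio
    dy[_I["glc_c"]] = kf * (p.glc_art - y[_I["glc_c"]]) - vr * (
        j["glc_transport_n"] + j["glc_transport_a"])
    dy[_I["lac_c"]] = kf * (p.lac_art - y[_I["lac_c"]]) - vr * j["mct_cn"]
    dy[_I["o2_c"]] = kf * (p.o2_art - y[_I["o2_c"]]) - vr * j["o2_transport"]
    dy[_I["bhb_c"]] = kf * (p.bhb_art - y[_I["bhb_c"]]) - vr * j["bhb_oxidation"]
    return dy


def metabolic_rhs(s: MetabolicState, p: MetabolicParams, demand: float) -> MetabolicState:
    """Time derivative of the state (returned as a MetabolicState of rates).

    ``demand`` (mM/ms, >= 0) is an external neuronal ATP consumption rate
    entering the atp_n equation as a sink.
    """
    if demand < 0:
        raise ValueError("demand must be >= 0")
    y = s.to_vector()
    j = metabolic_fluxes(y, p, demand)
    dy = _assemble(y, p, j)
    ck = j["creatine_kinase"]
    produced_rate = (2.0 * j["glycolysis_n"] + p.n_atp_ox * j["oxphos"]
                     + p.n_atp_shuttle * j["etc_shuttle"]
                     + p.n_atp_bhb * j["bhb_oxidation"] + max(ck, 0.0))
    return MetabolicState.from_vector(dy, atp_produced_cum=produced_rate)


def scale_mitochondria(p: MetabolicParams, layer_scale: float) -> MetabolicParams:
    """Multiply the oxidative-phosphorylation capacity by a layer-specific
    mitochondrial density factor; all other parameters unchanged."""
    if layer_scale <= 0:
        raise ValueError(f"layer_scale must be > 0, got {layer_scale}")
    return replace(p, mito_density_scale=p.mito_density_scale * layer_scale)


def resting_steady_state(
    p: MetabolicParams,
    demand_rest: Optional[float] = None,
    *,
    guess: Optional[MetabolicState] = None,
    tol: float = 1e-12,
    max_relax_ms: float = 2e7,
) -> MetabolicState:
    """Steady state of the NGV unit under a constant resting demand.

    Integrates toward equilibrium and polishes with a Newton solve; raises
    :class:`CalibrationError` if no state with ``max|dy/dt| < tol`` is found.
    With default parameters and demand the neuronal ATP settles at 1.38 mM.
    """
    if demand_rest is None:
        demand_rest = p.demand_rest
    if demand_rest < 0:
        raise ValueError("demand_rest must be >= 0")
    y0 = (guess or MetabolicState()).to_vector()

    def rhs(t, y):
        return _assemble(y, p, metabolic_fluxes(y, p, demand_rest))

    sol = solve_ivp(rhs, (0.0, max_relax_ms), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    y = sol.y[:, -1]

    best = y
    best_res = np.max(np.abs(rhs(0.0, y)))
    for method in ("hybr", "lm"):
        res = root(lambda v: rhs(0.0, v), best, method=method, tol=1e-14)
        cand_res = np.max(np.abs(rhs(0.0, res.x)))
        if cand_res < best_res and np.all(res.x >= -1e-9):
            best, best_res = res.x, cand_res
        if best_res <= tol:
            break
    if best_res > tol:
        raise CalibrationError(
            f"no steady state within tolerance {tol}; residual {best_res:.3e}")
    return MetabolicState.from_vector(np.maximum(best, 0.0))


def run_metabolism_segment(
    s: MetabolicState,
    p: MetabolicParams,
    demand: float,
    duration: float = 100.0,
) -> MetSegmentResult:
    """Integrate the NGV unit over one segment with a stiff solver.

    ``demand`` is held constant over the segment.  Cumulative production and
    metabolic sinks are integrated as additional states and neuronal ATP is
    reconstructed algebraically from them, so the energy-bookkeeping identity

        atp_n(t) = atp_n(0) + produced(t) - sinks(t) - demand * t

    holds to round-off by construction.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if demand < 0:
        raise ValueError("demand must be >= 0")
    s.validate(a_tot=p.a_tot)
    atp0 = s.atp_n
    i_atp = _I["atp_n"]
    yfull0 = s.to_vector()
    # auxiliary vector: all states except atp_n, then [produced_cum, sink_cum]
    idx_other = [i for i in range(len(STATE_NAMES)) if i != i_atp]
    z0 = np.concatenate([yfull0[idx_other], [0.0, 0.0]])

    def unpack(t, z):
        y = np.empty(len(STATE_NAMES))
        y[idx_other] = z[:-2]
        y[i_atp] = atp0 + z[-2] - z[-1] - demand * t
        return y

    def rhs(t, z):
        y = unpack(t, z)
        j = metabolic_fluxes(y, p, demand)
        dy = _assemble(y, p, j)
        ck = j["creatine_kinase"]
        produced = (2.0 * j["glycolysis_n"] + p.n_atp_ox * j["oxphos"]
                    + p.n_atp_shuttle * j["etc_shuttle"]
                    + p.n_atp_bhb * j["bhb_oxidation"] + max(ck, 0.0))
        sink = j["housekeeping_n"] + max(-ck, 0.0)
        return np.concatenate([dy[idx_other], [produced, sink]])

    sol = solve_ivp(rhs, (0.0, duration), z0, method=p.method,
                    rtol=p.rtol, atol=p.atol, dense_output=False)
    if not sol.success:
        raise MetabolicModelError(
            f"stiff solver failed at t={sol.t[-1]:.3f} ms: {sol.message}")

    z = sol.y[:, -1]
    y = unpack(duration, z)
    clamped = int(np.count_nonzero(y < 0))
    y = np.maximum(y, 0.0)
    produced = float(z[-2])
    final = MetabolicState.from_vector(
        y, atp_produced_cum=s.atp_produced_cum + produced)
    return MetSegmentResult(
        final_state=final,
        atp_produced=produced,
        atp_sink=float(z[-1]),
        n_steps=len(sol.t) - 1,
        n_rhs_evals=int(sol.nfev),
        clamp_events=clamped,
    )
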