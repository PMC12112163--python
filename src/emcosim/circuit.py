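"""Population construction: layers x e-type archetypes x surface areas.

Builds deterministic heterogeneous neuron populations emulating neocortical
microcircuit composition at desk scale.  Each of the eleven electrical types
(e-types) is represented by a single-compartment parameter archetype whose
qualitative firing class (adapting / tonic / stuttering / irregular /
delayed) arises from its conductance mix:

* adaptation          - slow M-type K+ current (g_m);
* burst onset         - high-voltage-activated Ca2+ current (g_ca);
* stuttering          - strong Ca2+-activated K+ current with slow Ca2+
                        clearance (g_kca, tau_ca), giving slow on/off cycling;
* delayed onset       - slowly inactivating D-type K+ current (g_d);
* irregular firing    - near-threshold drive with high relative noise.

Surface areas are drawn per archetype from a log-normal (standing in for
morphological diversity), and each neuron's metabolic parameters are scaled
by its layer's mitochondrial density factor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coupling import adp_from_atp
from .ephys import EphysParams, NeuronEphysState, init_state, run_batch_segment, \
    _ParamArrays, _StateArrays
from .metabolism import MetabolicParams, MetabolicState, resting_steady_state, \
    scale_mitochondria
from .stimulus import OUStimulusParams

__all__ = [
    "ETypeArchetype",
    "LayerSpec",
    "PopulationSpec",
    "Neuron",
    "ARCHETYPES",
    "E_TYPES",
    "build_population",
    "calibrate_stimulus",
    "fixture_population",
    "population_table",
]

E_TYPES = ("cADpyr", "cAC", "bAC", "cNAC", "bNAC", "dNAC",
           "dSTUT", "bIR", "cIR", "bSTUT", "cSTUT")


@dataclass(frozen=True)
class ETypeArchetype:
    name: str
    excitatory: bool
    firing_class: str  # adapting | tonic | stuttering | irregular | delayed
    template: EphysParams
    #: default relative OU drive (fractions of the cell's baseline current)
    ou_mean_frac: float = 0.8
    ou_amp_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.name not in E_TYPES:
            raise ValueError(f"unknown e-type {self.name!r}")
        if self.excitatory and self.name != "cADpyr":
            raise ValueError("only cADpyr is excitatory")


def _tmpl(**kw) -> EphysParams:
    return EphysParams(**kw)


#: the eleven e-type archetypes (conductances in mS/cm^2; baseline currents
#: in nA at the template area, chosen slightly above sustained rheobase)
ARCHETYPES: Dict[str, ETypeArchetype] = {
    "cADpyr": ETypeArchetype(
        "cADpyr", True, "adapting",
        _tmpl(area=2000.0, g_m=0.15, tau_max_m=12000.0, baseline_current=0.11),
        ou_mean_frac=0.258),
    "cAC": ETypeArchetype(
        "cAC", False, "adapting",
        _tmpl(area=1200.0, g_m=0.15, tau_max_m=12000.0, baseline_current=0.053),
        ou_mean_frac=0.245),
    "bAC": ETypeArchetype(
        "bAC", False, "adapting",
        _tmpl(area=1100.0, g_m=0.12, tau_max_m=8000.0, g_ca=0.06,
              baseline_current=0.040),
        ou_mean_frac=0.280),
    "cNAC": ETypeArchetype(
        "cNAC", False, "tonic",
        _tmpl(area=1200.0, g_m=0.0, baseline_current=0.010),
        ou_mean_frac=0.640, ou_amp_frac=0.15),
    "bNAC": ETypeArchetype(
        "bNAC", False, "tonic",
        _tmpl(area=1100.0, g_m=0.0, g_ca=0.06, baseline_current=0.008),
        ou_mean_frac=0.613),
    "dNAC": ETypeArchetype(
        "dNAC", False, "delayed",
        _tmpl(area=1200.0, g_m=0.0, g_d=1.2, baseline_current=0.045),
        ou_mean_frac=0.736),
    "dSTUT": ETypeArchetype(
        "dSTUT", False, "stuttering",
        _tmpl(area=1100.0, g_m=0.0, g_d=0.8, g_ca=0.12, g_kca=0.5,
              tau_ca=200.0, baseline_current=0.053),
        ou_mean_frac=0.815),
    "bIR": ETypeArchetype(
        "bIR", False, "irregular",
        _tmpl(area=1000.0, g_m=0.0, g_ca=0.15, g_kca=0.3, tau_ca=400.0,
              baseline_current=0.022),
        ou_mean_frac=0.477, ou_amp_frac=0.45),
    "cIR": ETypeArchetype(
        "cIR", False, "irregular",
        _tmpl(area=1000.0, g_m=0.0, g_ca=0.08, g_kca=0.25, tau_ca=500.0,
              baseline_current=0.021),
        ou_mean_frac=0.600, ou_amp_frac=0.45),
    "bSTUT": ETypeArchetype(
        "bSTUT", False, "stuttering",
        _tmpl(area=1100.0, g_m=0.0, g_ca=0.12, g_kca=0.5, tau_ca=200.0,
              baseline_current=0.034),
        ou_mean_frac=0.665),
    "cSTUT": ETypeArchetype(
        "cSTUT", False, "stuttering",
        _tmpl(area=1200.0, g_m=0.0, g_ca=0.10, g_kca=0.55, tau_ca=200.0,
              baseline_current=0.039),
        ou_mean_frac=0.764),
}


@dataclass(frozen=True)
class LayerSpec:
    """Composition of one cortical layer."""

    layer: int
    fraction: float  # of the total population
    exc_fraction: float
    mixture: Dict[str, float]  # e-type -> weight (sums to 1)
    mito_density_scale: float = 1.0
    stim_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.layer <= 6:
            raise ValueError("layer id must be in 1..6")
        w = sum(self.mixture.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"layer {self.layer} mixture weights sum to {w}, not 1")
        for name in self.mixture:
            if name not in E_TYPES:
                raise ValueError(f"unknown e-type {name!r} in layer {self.layer}")
        if self.layer == 1 and self.mixture.get("cADpyr", 0.0) > 0:
            raise ValueError("layer 1 contains no excitatory (cADpyr) cells")
        if self.layer == 1 and self.exc_fraction != 0.0:
            raise ValueError("layer 1 excitatory fraction must be 0")


@dataclass(frozen=True)
class PopulationSpec:
    total: int
    layers: Tuple[LayerSpec, ...]
    seed: int = 0
    name: str = "custom"
    area_sigma: float = 0.25  # log-normal sigma of surface areas

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be > 0")
        s = sum(ls.fraction for ls in self.layers)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"layer fractions sum to {s}, not 1")

    def config_hash(self) -> str:
        doc = {
            "total": self.total, "seed": self.seed, "name": self.name,
            "area_sigma": self.area_sigma,
            "layers": [
                {"layer": ls.layer, "fraction": ls.fraction,
                 "exc_fraction": ls.exc_fraction,
                 "mixture": dict(sorted(ls.mixture.items())),
                 "mito_density_scale": ls.mito_density_scale,
                 "stim_scale": ls.stim_scale}
                for ls in self.layers],
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


@dataclass
class Neuron:
    """One resolved neuron of a built population."""

    id: int
    layer: int
    etype: str
    eparams: EphysParams
    met_params: MetabolicParams
    stim: OUStimulusParams  # absolute units
    met_rest: MetabolicState  # layer resting steady state
    rng_stream: int

    def initial_ephys_state(self) -> NeuronEphysState:
        atp0 = self.met_rest.atp_n
        s = init_state(self.eparams, v0=-70.0, atp=atp0,
                       adp=adp_from_atp(atp0))
        return s

    def initial_met_state(self) -> MetabolicState:
        return replace(self.met_rest, atp_produced_cum=0.0)


def _largest_remainder(fractions: Sequence[float], total: int) -> List[int]:
    raw = np.asarray(fractions, dtype=float) * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def build_population(spec: PopulationSpec, seed: Optional[int] = None,
                     stim_overrides: Optional[Dict[int, OUStimulusParams]] = None,
                     met_base: Optional[MetabolicParams] = None) -> List[Neuron]:
    """Resolve a PopulationSpec into a deterministic list of neurons.

    Per-layer counts use largest-remainder rounding so they sum exactly to
    the requested total; the same scheme allocates e-types within a layer.
    Surface areas are drawn per-archetype from a log-normal around the
    template area.  ``stim_overrides`` maps layer -> relative OU parameters
    (e.g. from stimulus calibration).
    """
    seed = spec.seed if seed is None else seed
    met_base = met_base or MetabolicParams()
    counts = _largest_remainder([ls.fraction for ls in spec.layers], spec.total)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF, spawn_key=(0xC1C,)))

    # All NGV units start from the same reference resting state (solved at
    # mito scale 1); layer heterogeneity acts through the scaled parameters,
    # so layers with denser mitochondria genuinely run more oxidative flux.
    rest = resting_steady_state(met_base)
    neurons: List[Neuron] = []
    nid = 0
    for ls, n_layer in zip(spec.layers, counts):
        if n_layer == 0:
            continue
        etypes = sorted(ls.mixture)
        per_etype = _largest_remainder([ls.mixture[e] for e in etypes], n_layer)
        mp = scale_mitochondria(met_base, ls.mito_density_scale)
        for etype, n_e in zip(etypes, per_etype):
            arch = ARCHETYPES[etype]
            for _ in range(n_e):
                area = float(arch.template.area
                             * rng.lognormal(0.0, spec.area_sigma))
                ep = arch.template.with_area(area)
                gain = stim_overrides.get(ls.layer) if stim_overrides else None
                mean_frac = arch.ou_mean_frac * (gain.mean if gain else 1.0) \
                    * ls.stim_scale
                # noise amplitude scales with the mean drive, not the
                # characterisation baseline
                amp_frac = arch.ou_amp_frac * mean_frac \
                    * (gain.amplitude if gain else 1.0)
                stim = OUStimulusParams(
                    mean=mean_frac,
                    tau=gain.tau if gain else 3.0,
                    amplitude=amp_frac,
                    relative=True,
                ).resolve(ep.baseline_current)
                neurons.append(Neuron(
                    id=nid, layer=ls.layer, etype=etype, eparams=ep,
                    met_params=mp, stim=stim, met_rest=rest, rng_stream=nid))
                nid += 1
    assert len(neurons) == spec.total
    return neurons


def population_table(neurons: Sequence[Neuron]):
    """Summary DataFrame (id, layer, etype, area, seed stream)."""
    import pandas as pd

    return pd.DataFrame({
        "neuron_id": [n.id for n in neurons],
        "layer": [n.layer for n in neurons],
        "etype": [n.etype for n in neurons],
        "area_um2": [n.eparams.area for n in neurons],
        "rng_stream": [n.rng_stream for n in neurons],
    })


# ---------------------------------------------------------------------------
# stimulus calibration
# ---------------------------------------------------------------------------


def _probe_rates(neurons, gain_by_layer, dt, duration, seed,
                 fixed_atp=1.38, warmup: float = 0.0) -> Dict[int, float]:
    """Mean firing rate (Hz) per layer for given per-layer drive gains.

    Spikes during the first ``warmup`` ms are discarded so onset transients
    (initial bursts of adapting cells, silent periods of delayed cells) do
    not bias the steady firing-rate estimate."""
    pa = _ParamArrays([n.eparams for n in neurons])
    sa = _StateArrays([n.initial_ephys_state() for n in neurons])
    base = np.array([n.eparams.baseline_current for n in neurons])
    frac = np.array([ARCHETYPES[n.etype].ou_mean_frac for n in neurons])
    gain = np.array([gain_by_layer[n.layer] for n in neurons])
    mean = frac * gain * base
    amp = np.array([ARCHETYPES[n.etype].ou_amp_frac for n in neurons]) * mean
    tau = np.array([n.stim.tau for n in neurons])
    sa.ou_value = mean.copy()
    rngs = [np.random.Generator(np.random.Philox(np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF, spawn_key=(int(n.id), 0xCAB))))
        for n in neurons]
    out = run_batch_segment(sa, pa, mean, tau, amp, duration, dt, rngs,
                            fixed_atp=fixed_atp, record_stride=duration)
    rates: Dict[int, List[int]] = {}
    for n, s in zip(neurons, out["spikes"]):
        rates.setdefault(n.layer, []).append(int(np.sum(np.asarray(s) >= warmup)))
    return {ly: 1000.0 * np.mean(cnt) / (duration - warmup)
            for ly, cnt in rates.items()}


def calibrate_stimulus(
    neurons: Sequence[Neuron],
    target_rate_band: Tuple[float, float] = (1.0, 10.0),
    budget: int = 8,
    *,
    probe_duration: float = 1500.0,
    probe_warmup: float = 500.0,
    dt: float = 0.025,
    seed: int = 0,
) -> Tuple[Dict[int, OUStimulusParams], Dict[int, float], List[str]]:
    """Bisection on a per-layer OU drive gain toward a firing-rate band.

    Each archetype has its own relative operating drive (``ou_mean_frac`` of
    its baseline current); calibration scales all archetypes of a layer by a
    common multiplicative gain until the layer's mean firing rate over a
    short fixed-ATP probe falls inside ``target_rate_band``, or the budget
    is exhausted (the best gain found is then returned, with a warning).

    All layers are probed simultaneously.  Returns (per-layer relative
    OUStimulusParams whose mean/amplitude fields are the layer *gains* to be
    applied on top of the archetype fractions, achieved rates, warnings).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    lo_b, hi_b = target_rate_band
    layers = sorted({n.layer for n in neurons})
    lo = {ly: 0.0 for ly in layers}
    hi = {ly: None for ly in layers}
    cur = {ly: 1.0 for ly in layers}
    best = dict(cur)
    best_rates = {ly: np.nan for ly in layers}
    warnings: List[str] = []

    for _ in range(budget):
        rates = _probe_rates(neurons, cur, dt, probe_duration, seed,
                             warmup=probe_warmup)
        done = True
        for ly in layers:
            r = rates[ly]
            if np.isnan(best_rates[ly]) or not (lo_b <= best_rates[ly] <= hi_b):
                best[ly], best_rates[ly] = cur[ly], r
            if r < lo_b:
                lo[ly] = cur[ly]
                cur[ly] = cur[ly] * 2.0 if hi[ly] is None else 0.5 * (cur[ly] + hi[ly])
                done = False
            elif r > hi_b:
                hi[ly] = cur[ly]
                cur[ly] = 0.5 * (lo[ly] + cur[ly])
                done = False
            else:
                best[ly], best_rates[ly] = cur[ly], r
        if done:
            break
    for ly in layers:
        if not (lo_b <= best_rates[ly] <= hi_b):
            warnings.append(
                f"layer {ly}: target band {target_rate_band} Hz not reached "
                f"within budget (achieved {best_rates[ly]:.2f} Hz)")
    tau = float(np.mean([n.stim.tau for n in neurons]))
    out = {ly: OUStimulusParams(mean=best[ly], tau=tau, amplitude=1.0,
                                relative=True)
           for ly in layers}
    return out, best_rates, warnings


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _uniform_mixture(etypes: Sequence[str]) -> Dict[str, float]:
    w = 1.0 / len(etypes)
    mix = {e: w for e in etypes}
    # exact sum to 1
    mix[etypes[-1]] = 1.0 - w * (len(etypes) - 1)
    return mix


#: monotone mito-density profile with a layer-4 maximum
MITO_SCALES = {1: 0.90, 2: 0.97, 3: 1.03, 4: 1.10, 5: 1.02, 6: 0.95}


def _layer(layer, fraction, exc_fraction, mixture, stim_scale=1.0) -> LayerSpec:
    return LayerSpec(layer=layer, fraction=fraction, exc_fraction=exc_fraction,
                     mixture=mixture, mito_density_scale=MITO_SCALES[layer],
                     stim_scale=stim_scale)


def fixture_population(name: str) -> PopulationSpec:
    """Pinned-seed deterministic populations used in tests and examples.

    smoke  - 5 neurons spanning 5 archetypes in 2 layers;
    small  - 60 neurons over all 6 layers;
    medium - 300 neurons with the full 11-archetype mixture, balanced so
             every archetype has enough cells for per-group statistics.
    """
    inh = [e for e in E_TYPES if e != "cADpyr"]
    if name == "smoke":
        layers = (
            _layer(1, 0.2, 0.0, {"cNAC": 1.0}),
            _layer(2, 0.8, 0.5, _uniform_mixture(["cADpyr", "cAC", "bNAC", "cSTUT"])),
        )
        return PopulationSpec(total=5, layers=layers, seed=1201, name="smoke")
    if name == "small":
        layers = (
            _layer(1, 0.10, 0.0, _uniform_mixture(["cNAC", "cIR"])),
            _layer(2, 0.18, 0.5, _uniform_mixture(["cADpyr", "cAC", "bNAC"])),
            _layer(3, 0.18, 0.5, _uniform_mixture(["cADpyr", "bAC", "cSTUT"])),
            _layer(4, 0.18, 0.5, _uniform_mixture(["cADpyr", "cNAC", "dSTUT"])),
            _layer(5, 0.18, 0.5, _uniform_mixture(["cADpyr", "bSTUT", "bIR"])),
            _layer(6, 0.18, 0.5, _uniform_mixture(["cADpyr", "dNAC", "cAC"])),
        )
        return PopulationSpec(total=60, layers=layers, seed=1202, name="small")
    if name == "medium":
        layers = (
            _layer(1, 0.06, 0.0, _uniform_mixture(inh[:5])),
            _layer(2, 0.18, 0.45, {"cADpyr": 0.45, **{e: 0.055 for e in inh}}),
            _layer(3, 0.19, 0.45, {"cADpyr": 0.45, **{e: 0.055 for e in inh}}),
            _layer(4, 0.19, 0.45, {"cADpyr": 0.45, **{e: 0.055 for e in inh}}),
            _layer(5, 0.19, 0.45, {"cADpyr": 0.45, **{e: 0.055 for e in inh}}),
            _layer(6, 0.19, 0.45, {"cADpyr": 0.45, **{e: 0.055 for e in inh}}),
        )
        return PopulationSpec(total=300, layers=layers, seed=1203, name="medium")
    raise ValueError(f"unknown fixture {name!r}; expected smoke|small|medium")
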