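"""Single-compartment conductance-based neuron dynamics with an ATP-gated
sodium-potassium pump.

The membrane model is a Hodgkin-Huxley-type single compartment with transient
Na+, delayed-rectifier K+, a slow non-inactivating K+ (M) current for spike
frequency adaptation, a high-voltage-activated Ca2+ current, a Ca2+-activated
K+ current (slow burst/stutter dynamics), a slowly inactivating D-type K+
current (delayed firing onset), and leaks.  Intracellular Na+ and K+ are
dynamic and set their reversal potentials via Nernst; the Na+/K+-ATPase
extrudes 3 Na+ and imports 2 K+ per ATP hydrolysed and is the sole consumer
of ATP on the electrophysiology side.

Voltage and gates are advanced with a semi-implicit (exponential-Euler /
implicit-voltage) scheme at a fine fixed step (default 0.025 ms); the slow
ion and ATP pools are advanced explicitly at the same step.

All internal state arithmetic is vectorised over a batch of neurons; the
single-neuron operations are thin wrappers over a batch of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .constants import FARADAY, RTF_MV, UM2_TO_CM2, UM3_TO_L
from .stimulus import OUStimulusParams

__all__ = [
    "PumpParams",
    "EphysParams",
    "NeuronEphysState",
    "EphysSegmentResult",
    "NumericalInstabilityError",
    "pump_flux",
    "pump_cycle_rate",
    "ephys_step",
    "run_ephys_segment",
    "init_state",
    "sphere_volume_from_area",
    "GATE_NAMES",
]

GATE_NAMES = ("m", "h", "n", "p", "q", "d1", "d2")

#: default spike detection threshold (mV) and refractory window (ms)
SPIKE_THRESHOLD = -20.0
SPIKE_REFRACTORY = 2.0


class NumericalInstabilityError(RuntimeError):
    """Raised when the membrane state becomes non-finite during integration."""

    def __init__(self, neuron_id, time_ms):
        self.neuron_id = neuron_id
        self.time_ms = time_ms
        super().__init__(
            f"non-finite membrane state for neuron {neuron_id} at t={time_ms:.3f} ms"
        )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PumpParams:
    """Na+/K+-ATPase kinetics.

    The cycle rate is a product of saturable factors,

        rate = v_max * (na_i/(na_i+km_na))**3 * (k_o/(k_o+km_k))
                     * (atp/(atp+km_atp)) * sigm((v - v_half)/v_slope)

    in mM of ATP per ms (referred to the cell's intracellular volume), with
    the canonical 3 Na+ : 2 K+ : 1 ATP stoichiometry.  ``km_atp`` defaults to
    0.2 mM so the pump runs near-saturated at the physiological 1.38 mM ATP
    set-point.  The voltage factor operates on the lower tail of its sigmoid
    (v_half above the spike peak): consumption then scales ~exponentially
    with depolarisation, roughly tenfold over a spike excursion, while
    staying nearly flat across subthreshold voltages - this is what couples
    spiking to energy demand without distorting resting ion homeostasis.
    ``v_max`` is set so the resting cycle rate (at -70 mV, 10 mM Na+, 1.38 mM
    ATP) is 2e-5 mM/ms, matching the metabolic model's resting demand.
    """

    v_max: float = 5.847e-2  # mM ATP / ms at full saturation
    km_na: float = 10.0  # mM
    km_k: float = 1.5  # mM
    km_atp: float = 0.2  # mM
    v_half: float = 40.0  # mV
    v_slope: float = 20.0  # mV

    def __post_init__(self) -> None:
        for name in ("km_na", "km_k", "km_atp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v_max < 0:
            raise ValueError("v_max must be >= 0")


def sphere_volume_from_area(area_um2: float) -> float:
    """Volume (um^3) of the sphere with the given surface area (um^2)."""
    r = np.sqrt(area_um2 / (4.0 * np.pi))
    return float(4.0 / 3.0 * np.pi * r**3)


@dataclass(frozen=True)
class EphysParams:
    """Biophysical parameters of one single-compartment neuron.

    Conductances are densities in mS/cm^2; capacitance in uF/cm^2; area in
    um^2 and volume in um^3.  Extracellular K+ and Ca2+ are fixed (5 mM and
    1.1 mM by default) throughout a simulation.
    """

    cm: float = 1.0
    area: float = 1500.0
    volume: Optional[float] = None  # derived from area if None

    g_leak: float = 0.05
    e_leak: float = -70.0
    g_na: float = 50.0
    g_kd: float = 5.0
    v_t: float = -55.0  # spike-threshold shift of the Na/Kd kinetics
    g_m: float = 0.0
    tau_max_m: float = 1000.0
    g_ca: float = 0.0
    e_ca: float = 120.0
    g_kca: float = 0.0
    kd_kca: float = 4e-4  # mM
    tau_ca: float = 150.0  # ms
    ca_rest: float = 5e-5  # mM
    ca_gamma: float = 0.02  # fraction of Ca current reaching the bulk pool
    g_d: float = 0.0
    tau_d2: float = 600.0
    g_na_leak: float = 0.015
    tau_cl: float = 500.0
    cl_rest: float = 6.0

    na_o: float = 140.0
    k_o: float = 5.0
    ca_o: float = 1.1
    temperature: float = 34.0

    pump: PumpParams = field(default_factory=PumpParams)
    atp_floor: float = 1e-6
    baseline_current: float = 0.25  # nA; reference drive near rheobase

    def __post_init__(self) -> None:
        for name in ("g_leak", "g_na", "g_kd", "g_m", "g_ca", "g_kca", "g_d", "g_na_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if self.volume is None:
            object.__setattr__(self, "volume", sphere_volume_from_area(self.area))
        if self.volume <= 0:
            raise ValueError("volume must be > 0")

    def with_area(self, area_um2: float) -> "EphysParams":
        """Copy with a new surface area.

        The volume is re-derived (sphere-equivalent), the baseline drive
        scales with area (larger cells need more current), and the pump's
        maximal concentration rate scales with the surface-to-volume ratio:
        pump sites sit in the membrane, so the rate of change of a bulk
        concentration they produce transforms like every other membrane
        flux (~ area / volume).
        """
        scale = area_um2 / self.area
        vol = sphere_volume_from_area(area_um2)
        sv_scale = (area_um2 / vol) / (self.area / self.volume)
        return replace(
            self,
            area=area_um2,
            volume=vol,
            baseline_current=self.baseline_current * scale,
            pump=replace(self.pump, v_max=self.pump.v_max * sv_scale),
        )


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class NeuronEphysState:
    """Electrophysiological state of one neuron."""

    v: float = -70.0
    gates: Dict[str, float] = field(default_factory=dict)
    na_i: float = 10.0
    k_i: float = 140.0
    ca_i: float = 5e-5
    cl_i: float = 6.0
    atp: float = 1.38
    adp: float = 0.057
    atp_consumed_cum: float = 0.0
    ou_value: float = 0.0

    def validate(self, total_adenine: Optional[float] = None) -> None:
        for name in ("na_i", "k_i", "ca_i", "cl_i", "atp", "adp"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")
        for g, x in self.gates.items():
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gate {g} out of [0,1]: {x}")
        if total_adenine is not None and self.atp > total_adenine + 1e-12:
            raise ValueError(f"atp={self.atp} exceeds total adenine pool {total_adenine}")


@dataclass
class EphysSegmentResult:
    """Traces and bookkeeping for one electrophysiology segment."""

    final_state: NeuronEphysState
    t: np.ndarray
    v: np.ndarray
    na_i: np.ndarray
    k_i: np.ndarray
    atp: np.ndarray
    atp_consumed_trace: np.ndarray
    spikes: np.ndarray
    atp_consumed: float
    clamp_events: int = 0


# ---------------------------------------------------------------------------
# channel kinetics (rate functions at 34 degC)
# ---------------------------------------------------------------------------


def _linoid(u, k):
    """u / (1 - exp(-u/k)), continuous through u = 0 (limit k)."""
    u = np.asarray(u, dtype=float)
    x = np.minimum(np.maximum(u / k, -50.0), 50.0)
    small = np.abs(x) < 1e-6
    denom = 1.0 - np.exp(-x)
    denom[small] = 1.0
    return np.where(small, k * (1.0 + x / 2.0), u / denom)


def _safe_exp(x):
    return np.exp(np.minimum(np.maximum(x, -60.0), 60.0))


def gate_rates(v, p_vt, tau_max_m, tau_d2):
    """Steady states and time constants of all gates at voltage ``v``.

    Returns dict name -> (x_inf, tau).  Na/Kd kinetics follow the classic
    threshold-shifted cortical formulation; the M current and the D-type
    K+ current use sigmoidal steady states with slow time constants.
    """
    vm = v - p_vt
    a_m = 0.32 * _linoid(vm - 13.0, 4.0)
    b_m = 0.28 * _linoid(-(vm - 40.0), 5.0)
    a_h = 0.128 * _safe_exp(-(vm - 17.0) / 18.0)
    b_h = 4.0 / (1.0 + _safe_exp(-(vm - 40.0) / 5.0))
    a_n = 0.032 * _linoid(vm - 15.0, 5.0)
    b_n = 0.5 * _safe_exp(-(vm - 10.0) / 40.0)

    p_inf = 1.0 / (1.0 + _safe_exp(-(v + 35.0) / 10.0))
    tau_p = tau_max_m / (3.3 * _safe_exp((v + 35.0) / 20.0) + _safe_exp(-(v + 35.0) / 20.0))

    a_q = 0.055 * _linoid(v + 27.0, 3.8)
    b_q = 0.94 * _safe_exp(-(v + 75.0) / 17.0)

    d1_inf = 1.0 / (1.0 + _safe_exp(-(v + 50.0) / 10.0))
    d2_inf = 1.0 / (1.0 + _safe_exp((v + 70.0) / 6.0))

    def ab(a, b):
        tau = 1.0 / (a + b)
        return a * tau, tau

    out = {}
    out["m"], out["h"], out["n"] = ab(a_m, b_m), ab(a_h, b_h), ab(a_n, b_n)
    out["p"] = (p_inf, tau_p)
    out["q"] = ab(a_q, b_q)
    out["d1"] = (d1_inf, np.full_like(np.asarray(v, dtype=float), 2.0))
    out["d2"] = (d2_inf, np.full_like(np.asarray(v, dtype=float), tau_d2))
    return out


# ---------------------------------------------------------------------------
# pump
# ---------------------------------------------------------------------------


def pump_cycle_rate(v, na_i, k_o, atp, p: PumpParams):
    """ATP hydrolysis rate of the Na+/K+-ATPase (mM/ms), monotone
    non-decreasing in each of na_i, k_o and atp."""
    for name, val in (("na_i", na_i), ("k_o", k_o), ("atp", atp)):
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"negative concentration for {name}")
    fna = (na_i / (na_i + p.km_na)) ** 3
    fk = k_o / (k_o + p.km_k)
    fatp = atp / (atp + p.km_atp)
    fv = 1.0 / (1.0 + _safe_exp(-(v - p.v_half) / p.v_slope))
    return p.v_max * fna * fk * fatp * fv


def pump_flux(v, na_i, k_o, atp, p: PumpParams):
    """(na_efflux, k_influx, atp_rate) in mM/ms: 3 Na out, 2 K in, 1 ATP."""
    rate = pump_cycle_rate(v, na_i, k_o, atp, p)
    return 3.0 * rate, 2.0 * rate, rate


# ---------------------------------------------------------------------------
# batched internals
# ---------------------------------------------------------------------------


class _ParamArrays:
    """Columnar view of a list of EphysParams."""

    _SCALAR_FIELDS = (
        "cm", "area", "volume", "g_leak", "e_leak", "g_na", "g_kd", "v_t",
        "g_m", "tau_max_m", "g_ca", "e_ca", "g_kca", "kd_kca", "tau_ca",
        "ca_rest", "ca_gamma", "g_d", "tau_d2", "g_na_leak", "tau_cl",
        "cl_rest", "na_o", "k_o", "ca_o", "atp_floor", "baseline_current",
    )
    _PUMP_FIELDS = ("v_max", "km_na", "km_k", "km_atp", "v_half", "v_slope")

    def __init__(self, params: Sequence[EphysParams]):
        for f_ in self._SCALAR_FIELDS:
            setattr(self, f_, np.array([getattr(p, f_) for p in params], dtype=float))
        for f_ in self._PUMP_FIELDS:
            setattr(self, "pump_" + f_,
                    np.array([getattr(p.pump, f_) for p in params], dtype=float))
        area_cm2 = self.area * UM2_TO_CM2
        vol_l = self.volume * UM3_TO_L
        #: uA/cm^2 -> mM/ms for the carried (monovalent) ion
        self.i_to_flux = area_cm2 * 1e-6 / (FARADAY * vol_l)
        #: nA -> uA/cm^2
        self.nA_to_density = 1e-3 / area_cm2
        #: mM/ms (+1 charge) -> uA/cm^2
        self.flux_to_i = 1.0 / self.i_to_flux
        self.n = len(params)
        #: packed rows for the compiled kernel (row order fixed in _kernel.py)
        self.packed = np.vstack([
            self.cm, self.g_leak, self.e_leak, self.g_na, self.g_kd, self.v_t,
            self.g_m, self.tau_max_m, self.g_ca, self.e_ca, self.g_kca,
            self.kd_kca, self.tau_ca, self.ca_rest, self.ca_gamma, self.g_d,
            self.tau_d2, self.g_na_leak, self.tau_cl, self.cl_rest, self.na_o,
            self.k_o, self.atp_floor, self.pump_v_max, self.pump_km_na,
            self.pump_km_k, self.pump_km_atp, self.pump_v_half,
            self.pump_v_slope, self.i_to_flux, self.nA_to_density,
            self.flux_to_i,
        ])


class _StateArrays:
    FIELDS = ("v", "na_i", "k_i", "ca_i", "cl_i", "atp", "adp",
              "atp_consumed_cum", "ou_value", "clamp_adjust")

    def __init__(self, states: Sequence[NeuronEphysState]):
        for f_ in self.FIELDS:
            if f_ == "clamp_adjust":
                self.clamp_adjust = np.zeros(len(states))
            else:
                setattr(self, f_, np.array([getattr(s, f_) for s in states], dtype=float))
        self.gates = np.array(
            [[s.gates[g] for s in states] for g in GATE_NAMES], dtype=float
        )

    def to_states(self) -> List[NeuronEphysState]:
        out = []
        for i in range(len(self.v)):
            out.append(NeuronEphysState(
                v=float(self.v[i]),
                gates={g: float(self.gates[j, i]) for j, g in enumerate(GATE_NAMES)},
                na_i=float(self.na_i[i]), k_i=float(self.k_i[i]),
                ca_i=float(self.ca_i[i]), cl_i=float(self.cl_i[i]),
                atp=float(self.atp[i]), adp=float(self.adp[i]),
                atp_consumed_cum=float(self.atp_consumed_cum[i]),
                ou_value=float(self.ou_value[i]),
            ))
        return out


def _batch_pump_rate(v, na_i, atp, pa: _ParamArrays):
    fna = (na_i / (na_i + pa.pump_km_na)) ** 3
    fk = pa.k_o / (pa.k_o + pa.pump_km_k)
    fatp = atp / (atp + pa.pump_km_atp)
    fv = 1.0 / (1.0 + _safe_exp(-(v - pa.pump_v_half) / pa.pump_v_slope))
    return pa.pump_v_max * fna * fk * fatp * fv


def _gate_inf_tau(v, pa: _ParamArrays, inf: np.ndarray, tau: np.ndarray) -> None:
    """Fill (7, n) steady-state and time-constant buffers for all gates."""
    vm = v - pa.v_t
    a = 0.32 * _linoid(vm - 13.0, 4.0)
    b = 0.28 * _linoid(-(vm - 40.0), 5.0)
    tau[0] = 1.0 / (a + b)
    inf[0] = a * tau[0]
    a = 0.128 * _safe_exp(-(vm - 17.0) / 18.0)
    b = 4.0 / (1.0 + _safe_exp(-(vm - 40.0) / 5.0))
    tau[1] = 1.0 / (a + b)
    inf[1] = a * tau[1]
    a = 0.032 * _linoid(vm - 15.0, 5.0)
    b = 0.5 * _safe_exp(-(vm - 10.0) / 40.0)
    tau[2] = 1.0 / (a + b)
    inf[2] = a * tau[2]
    ev = _safe_exp((v + 35.0) / 20.0)
    inf[3] = 1.0 / (1.0 + _safe_exp(-(v + 35.0) / 10.0))
    tau[3] = pa.tau_max_m / (3.3 * ev + 1.0 / ev)
    a = 0.055 * _linoid(v + 27.0, 3.8)
    b = 0.94 * _safe_exp(-(v + 75.0) / 17.0)
    tau[4] = 1.0 / (a + b)
    inf[4] = a * tau[4]
    inf[5] = 1.0 / (1.0 + _safe_exp(-(v + 50.0) / 10.0))
    tau[5] = 2.0
    inf[6] = 1.0 / (1.0 + _safe_exp((v + 70.0) / 6.0))
    tau[6] = pa.tau_d2


def _batch_step(sa: _StateArrays, pa: _ParamArrays, i_stim_nA, dt: float,
                fixed_atp: Optional[float],
                work: Optional[tuple] = None) -> None:
    """Advance all neurons by one fine step (in place)."""
    v = sa.v
    # pump at pre-step state
    rate = _batch_pump_rate(v, sa.na_i, sa.atp, pa)

    # gates: exponential (semi-implicit) update at the pre-step voltage
    if work is None:
        work = (np.empty((7, pa.n)), np.empty((7, pa.n)))
    inf, tau = work
    _gate_inf_tau(v, pa, inf, tau)
    sa.gates += (inf - sa.gates) * -np.expm1(-dt / tau)
    m, h, n, p, q, d1, d2 = sa.gates

    ena = RTF_MV * np.log(pa.na_o / sa.na_i)
    ek = RTF_MV * np.log(pa.k_o / sa.k_i)

    g_na_tot = pa.g_na * m**3 * h + pa.g_na_leak
    g_k_tot = (pa.g_kd * n**4 + pa.g_m * p
               + pa.g_kca * sa.ca_i / (sa.ca_i + pa.kd_kca)
               + pa.g_d * d1 * d2)
    g_ca_eff = pa.g_ca * q**2

    i_pump = rate * pa.flux_to_i  # net +1 charge out per cycle, uA/cm^2
    g_tot = pa.g_leak + g_na_tot + g_k_tot + g_ca_eff
    b = (pa.g_leak * pa.e_leak + g_na_tot * ena + g_k_tot * ek
         + g_ca_eff * pa.e_ca + i_stim_nA * pa.nA_to_density - i_pump)
    # implicit voltage update: cm dv/dt = -g_tot v + b
    a = pa.cm / dt
    v_new = (a * v + b) / (a + g_tot)
    sa.v = v_new

    i_na = g_na_tot * (v_new - ena)
    i_k = g_k_tot * (v_new - ek)
    i_ca = g_ca_eff * (v_new - pa.e_ca)

    sa.na_i += dt * (-i_na * pa.i_to_flux - 3.0 * rate)
    sa.k_i += dt * (-i_k * pa.i_to_flux + 2.0 * rate)
    sa.ca_i += dt * (-i_ca * pa.i_to_flux * 0.5 * pa.ca_gamma
                     - (sa.ca_i - pa.ca_rest) / pa.tau_ca)
    np.maximum(sa.ca_i, 0.0, out=sa.ca_i)
    sa.cl_i += dt * (-(sa.cl_i - pa.cl_rest) / pa.tau_cl)

    if fixed_atp is not None:
        sa.atp_consumed_cum += rate * dt
        sa.atp[:] = fixed_atp
    else:
        new_atp = sa.atp - rate * dt
        clipped = np.maximum(new_atp, pa.atp_floor)
        sa.clamp_adjust += clipped - new_atp
        sa.atp_consumed_cum += sa.atp - clipped
        sa.atp = clipped


try:
    from ._kernel import segment_kernel as _segment_kernel
    _HAVE_KERNEL = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_KERNEL = False


def run_batch_segment(
    sa: _StateArrays,
    pa: _ParamArrays,
    ou_mean: np.ndarray,
    ou_tau: np.ndarray,
    ou_amp: np.ndarray,
    duration: float,
    dt: float,
    rngs: Sequence[np.random.Generator],
    *,
    t0: float = 0.0,
    record_stride: float = 0.5,
    fixed_atp: Optional[float] = None,
    spike_threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    neuron_ids: Optional[Sequence[int]] = None,
    use_kernel: Optional[bool] = None,
):
    """Advance a batch of neurons by ``duration`` ms, mutating ``sa``.

    Per-neuron OU noise is drawn from per-neuron generators so results do not
    depend on how neurons are scheduled across workers.  Returns a dict with
    recorded traces (at ``record_stride``), per-neuron spike-time lists and
    the per-neuron ATP consumed over the segment.

    The inner loop runs in a compiled kernel when available; the pure-numpy
    path (``use_kernel=False``) implements the identical update and is kept
    as a cross-validation reference.
    """
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError(f"duration {duration} is not a multiple of dt {dt}")
    nn = pa.n
    consumed0 = sa.atp_consumed_cum.copy()

    stride_steps = max(1, int(round(record_stride / dt)))
    rec_idx = np.arange(stride_steps, n_steps + 1, stride_steps, dtype=np.int64)
    rec_t = t0 + rec_idx * dt
    n_rec = len(rec_idx)

    noise = np.empty((n_steps, nn)) if n_steps else np.empty((0, nn))
    for i, rng in enumerate(rngs):
        noise[:, i] = rng.standard_normal(n_steps)

    ids = neuron_ids if neuron_ids is not None else list(range(nn))
    if use_kernel is None:
        use_kernel = _HAVE_KERNEL

    if use_kernel:
        S = np.vstack([sa.v, sa.na_i, sa.k_i, sa.ca_i, sa.cl_i, sa.atp,
                       sa.atp_consumed_cum, sa.clamp_adjust, sa.ou_value])
        G = sa.gates.copy()
        rec_out = np.empty((5, n_rec, nn))
        cap = max(8, int(duration / refractory) + 2)
        spike_times = np.empty((nn, cap))
        spike_counts = np.zeros(nn, dtype=np.int64)
        status, t_fail = _segment_kernel(
            S, G, pa.packed, ou_mean.astype(float), ou_tau.astype(float),
            ou_amp.astype(float), noise, float(dt), n_steps,
            fixed_atp is not None,
            float(fixed_atp) if fixed_atp is not None else 0.0,
            rec_idx, rec_out, spike_times, spike_counts, float(t0),
            float(spike_threshold), float(refractory))
        (sa.v, sa.na_i, sa.k_i, sa.ca_i, sa.cl_i, sa.atp,
         sa.atp_consumed_cum, sa.clamp_adjust, sa.ou_value) = S
        sa.gates = G
        if status:
            raise NumericalInstabilityError(ids[status - 1], t_fail)
        rec = {k: rec_out[j] for j, k in enumerate(
            ("v", "na_i", "k_i", "atp", "atp_consumed_cum"))}
        spikes = [spike_times[i, :spike_counts[i]].copy() for i in range(nn)]
        return {
            "t": rec_t,
            "traces": rec,
            "spikes": spikes,
            "atp_consumed": sa.atp_consumed_cum - consumed0,
        }

    rec = {k: np.empty((n_rec, nn)) for k in ("v", "na_i", "k_i", "atp", "atp_consumed_cum")}
    sqrt_dt = np.sqrt(dt)
    spikes: List[List[float]] = [[] for _ in range(nn)]
    last_spike = np.full(nn, -np.inf)
    r = 0
    work = (np.empty((7, nn)), np.empty((7, nn)))
    for k in range(n_steps):
        # OU stimulus advances first; its value drives this step
        sa.ou_value += (ou_mean - sa.ou_value) * (dt / ou_tau) + ou_amp * sqrt_dt * noise[k]
        v_prev = sa.v
        _batch_step(sa, pa, sa.ou_value, dt, fixed_atp, work)
        t = t0 + (k + 1) * dt
        crossed = (sa.v >= spike_threshold) & (v_prev < spike_threshold) & \
            (t - last_spike >= refractory)
        if crossed.any():
            for i in np.nonzero(crossed)[0]:
                ts = t - dt * (sa.v[i] - spike_threshold) / (sa.v[i] - v_prev[i])
                spikes[i].append(ts)
                last_spike[i] = t
        if not np.all(np.isfinite(sa.v)):
            bad = int(np.nonzero(~np.isfinite(sa.v))[0][0])
            raise NumericalInstabilityError(ids[bad], t)
        if r < n_rec and k + 1 == rec_idx[r]:
            for key in rec:
                rec[key][r] = getattr(sa, key)
            r += 1

    return {
        "t": rec_t,
        "traces": rec,
        "spikes": [np.array(s) for s in spikes],
        "atp_consumed": sa.atp_consumed_cum - consumed0,
    }


# ---------------------------------------------------------------------------
# single-neuron API
# ---------------------------------------------------------------------------


def init_state(p: EphysParams, v0: float = -70.0, atp: float = 1.38,
               adp: float = 0.057) -> NeuronEphysState:
    """State with all gates at their steady value for ``v0``."""
    rates = gate_rates(np.array([v0]), p.v_t, p.tau_max_m, p.tau_d2)
    gates = {g: float(rates[g][0][0]) for g in GATE_NAMES}
    return NeuronEphysState(v=v0, gates=gates, ca_i=p.ca_rest, cl_i=p.cl_rest,
                            atp=atp, adp=adp)


def ephys_step(s: NeuronEphysState, p: EphysParams, i_stim: float, dt: float,
               fixed_atp: Optional[float] = None) -> NeuronEphysState:
    """One fine step for a single neuron; returns the new state."""
    s.validate()
    sa = _StateArrays([s])
    pa = _ParamArrays([p])
    _batch_step(sa, pa, np.array([i_stim]), dt, fixed_atp)
    if not np.isfinite(sa.v[0]):
        raise NumericalInstabilityError(0, dt)
    return sa.to_states()[0]


def run_ephys_segment(
    s: NeuronEphysState,
    p: EphysParams,
    stim: OUStimulusParams,
    duration: float,
    dt: float = 0.025,
    rng: Optional[np.random.Generator] = None,
    *,
    record_stride: float = 0.1,
    fixed_atp: Optional[float] = None,
    t0: float = 0.0,
) -> EphysSegmentResult:
    """Integrate one neuron for ``duration`` ms under an OU stimulus."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError(f"duration {duration} is not a multiple of dt {dt}")
    if rng is None:
        rng = np.random.default_rng(0)
    stim = stim.resolve(p.baseline_current)
    sa = _StateArrays([s])
    pa = _ParamArrays([p])
    out = run_batch_segment(
        sa, pa,
        np.array([stim.mean]), np.array([stim.tau]), np.array([stim.amplitude]),
        duration, dt, [rng], t0=t0, record_stride=record_stride,
        fixed_atp=fixed_atp,
    )
    final = sa.to_states()[0]
    return EphysSegmentResult(
        final_state=final,
        t=out["t"],
        v=out["traces"]["v"][:, 0],
        na_i=out["traces"]["na_i"][:, 0],
        k_i=out["traces"]["k_i"][:, 0],
        atp=out["traces"]["atp"][:, 0],
        atp_consumed_trace=out["traces"]["atp_consumed_cum"][:, 0],
        spikes=out["spikes"][0],
        atp_consumed=float(out["atp_consumed"][0]),
        clamp_events=int(np.count_nonzero(sa.clamp_adjust)),
    )
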