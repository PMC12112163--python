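"""Multirate co-simulation orchestrator.

Electrophysiology advances at a fine fixed step (0.025 ms) and metabolism
with a stiff solver over long segments; the two exchange ATP at coupling
intervals equal to the smallest common multiple of the simulator steps
(100 ms by default).  At each synchronisation the neuronal ATP is merged by
the additive splitting rule

    ATP_j = ATP_ephys,j + ATP_met,j - ATP_{j-1}

which credits the decrement (pump consumption) from the electrophysiology
side and the increment (production) from the metabolism side over the same
interval.  ADP is then overwritten in both simulators from the adenylate
kinase equilibrium (2 ADP <-> ATP + AMP with constant q_AK over a fixed
total adenine pool A):

    ADP = (ATP/2) * (-q_AK + sqrt(q_AK^2 + 4 q_AK (A/ATP - 1)))

The orchestrator also owns the sanity checks (species kept within
configurable bounds, clamp-and-log policy) and the fixed-ATP reference mode
in which metabolism is inactive and ATP is held at 1.38 mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ephys import _ParamArrays, _StateArrays, run_batch_segment
from .metabolism import MetabolicState, run_metabolism_segment

__all__ = [
    "CouplingConstants",
    "CouplingRecord",
    "SimulationResult",
    "sync_atp",
    "adp_from_atp",
    "sync_schedule",
    "run_coupled",
    "sanity_check",
    "DEFAULT_BOUNDS",
]

#: species -> (min, max) sanity limits checked at every synchronisation
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "v": (-120.0, 70.0),
    "na_i": (2.0, 60.0),
    "k_i": (50.0, 180.0),
    "atp": (0.0, 1.44),
    "adp": (0.0, 1.44),
    "ca_i": (0.0, 0.05),
    "cl_i": (0.0, 40.0),
}


@dataclass(frozen=True)
class CouplingConstants:
    """Constants of the synchronisation scheme.

    A is the total adenine nucleotide concentration (~1.44 mM) and q_ak the
    adenylate kinase equilibrium constant (0.92).  ``t_coupling`` must be a
    common multiple of both simulator steps.
    """

    a_tot: float = 1.44  # mM
    q_ak: float = 0.92
    t_coupling: float = 100.0  # ms
    dt_ephys: float = 0.025  # ms
    dt_met: float = 100.0  # ms (metabolism macro step = segment length)
    atp_epsilon: float = 1e-6  # mM, lower clamp
    fixed_atp_value: float = 1.38  # mM, reference mode
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        if self.a_tot <= 0 or self.q_ak <= 0:
            raise ValueError("a_tot and q_ak must be > 0")
        for name in ("t_coupling", "dt_ephys", "dt_met"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CouplingRecord:
    """Per-synchronisation ATP bookkeeping (arrays over neurons)."""

    j: int
    t: float
    atp_prev: np.ndarray
    atp_ephys: np.ndarray
    atp_met: np.ndarray
    atp_merged: np.ndarray
    adp_merged: np.ndarray
    n_clamped: int = 0


@dataclass
class SanityEvent:
    neuron_id: int
    species: str
    value: float
    bound: Tuple[float, float]
    t: float = float("nan")


@dataclass
class SimulationResult:
    """Full output of a (co-)simulation run."""

    t: np.ndarray
    traces: Dict[str, np.ndarray]  # name -> (n_times, n_neurons)
    spikes: List[np.ndarray]
    coupling: Optional[List[CouplingRecord]]
    energy: Dict[str, np.ndarray]
    sanity_events: List[SanityEvent]
    meta: Dict[str, object]
    final_ephys: Dict[str, np.ndarray] = field(default_factory=dict)
    final_met_states: Optional[List[MetabolicState]] = None

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    def spike_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])


# ---------------------------------------------------------------------------
# synchronisation primitives
# ---------------------------------------------------------------------------


def sync_atp(atp_prev, atp_ephys, atp_met, c: Optional[CouplingConstants] = None):
    """Additive-splitting merge of the two simulators' ATP values,

        merged = atp_ephys + atp_met - atp_prev,

    floored at the epsilon clamp (a logged sanity event; the orchestrator
    additionally caps the value injected into the simulators at the adenine
    pool A).  When one side did not move, the other side's value passes
    through bit-exactly, so degenerate runs reproduce the single-simulator
    trajectory.  Returns ``(merged, clamp_adjust)``; accepts scalars or
    arrays.
    """
    c = c or CouplingConstants()
    prev = np.asarray(atp_prev, dtype=float)
    e = np.asarray(atp_ephys, dtype=float)
    m = np.asarray(atp_met, dtype=float)
    if np.any(~np.isfinite(e + m - prev)) or np.any(prev < 0):
        raise ValueError("sync_atp requires finite, non-negative inputs")
    raw = np.where(m == prev, e, np.where(e == prev, m, e + m - prev))
    merged = np.maximum(raw, c.atp_epsilon)
    adjust = merged - raw
    if np.ndim(atp_prev) == 0 and np.ndim(atp_ephys) == 0 and np.ndim(atp_met) == 0:
        return float(merged), float(adjust)
    return merged, adjust


def adp_from_atp(atp, c: Optional[CouplingConstants] = None):
    """ADP closed by the adenylate-kinase equilibrium at the given ATP.

    Satisfies ADP^2 = q_AK * ATP * AMP with AMP = A - ATP - ADP; zero at
    ATP = A (the whole pool is phosphorylated) and strictly decreasing in
    ATP on the physiological high-energy branch.  Raises for ATP outside
    (0, A].
    """
    c = c or CouplingConstants()
    atp_arr = np.asarray(atp, dtype=float)
    if np.any(atp_arr <= 0) or np.any(atp_arr > c.a_tot * (1 + 1e-12)):
        raise ValueError(f"atp must lie in (0, {c.a_tot}]")
    q = c.q_ak
    ratio = np.maximum(c.a_tot / atp_arr - 1.0, 0.0)
    adp = (atp_arr / 2.0) * (-q + np.sqrt(q * q + 4.0 * q * ratio))
    if np.ndim(atp) == 0:
        return float(adp)
    return adp


def sync_schedule(T: float, c: CouplingConstants, dt_met: Optional[float] = None
                  ) -> List[float]:
    """Synchronisation times: multiples of the smallest common multiple of
    the two simulator steps, up to and including T."""
    if T <= 0:
        raise ValueError("T must be > 0")
    dt_met = dt_met if dt_met is not None else c.dt_met
    fe = Fraction(c.dt_ephys).limit_denominator(10**9)
    fm = Fraction(dt_met).limit_denominator(10**9)
    # lcm of two rationals a/b, c/d = lcm(a*d, c*b) / (b*d)
    num = math.lcm(fe.numerator * fm.denominator, fm.numerator * fe.denominator)
    scm_ms = float(Fraction(num, fe.denominator * fm.denominator))
    if scm_ms > T + 1e-9:
        raise ValueError(
            f"simulator steps {c.dt_ephys} and {dt_met} have no common "
            f"multiple below T={T}")
    n = T / scm_ms
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"T={T} is not a multiple of the sync interval {scm_ms}")
    return [scm_ms * k for k in range(1, int(round(n)) + 1)]


def sanity_check(state, bounds: Dict[str, Tuple[float, float]],
                 neuron_id: int = 0, t: float = float("nan")) -> List[SanityEvent]:
    """Check the species of a state-like object against bounds.

    ``state`` may be a NeuronEphysState, MetabolicState or mapping; species
    missing from the state are skipped.  Never mutates the state.
    """
    out = []
    for species, (lo, hi) in bounds.items():
        if isinstance(state, dict):
            if species not in state:
                continue
            val = state[species]
        else:
            if not hasattr(state, species):
                continue
            val = getattr(state, species)
        if not (lo <= val <= hi):
            out.append(SanityEvent(neuron_id, species, float(val), (lo, hi), t))
    return out


# ---------------------------------------------------------------------------
# coupled run
# ---------------------------------------------------------------------------


def _metabolism_task(args):
    state, params, duration = args
    r = run_metabolism_segment(state, params, demand=0.0, duration=duration)
    return r.final_state, r.atp_produced, r.atp_sink, r.clamp_events


def run_coupled(
    population,
    T: float,
    c: Optional[CouplingConstants] = None,
    mode: str = "coupled",
    seed: int = 0,
    *,
    record_stride: float = 0.5,
    workers: int = 1,
) -> SimulationResult:
    """Run the multirate co-simulation for a built population.

    ``population`` is a sequence of circuit Neuron objects (each carrying
    resolved electrophysiological and metabolic parameters, an absolute OU
    stimulus and an initial metabolic state).  ``mode`` is ``"coupled"`` or
    ``"fixed_atp"``; in the reference mode metabolism is skipped and ATP is
    held at 1.38 mM while consumption is still tallied.

    Each neuron draws its stimulus noise from its own counter-based stream
    keyed on (seed, neuron id), so results are independent of worker
    scheduling; per-neuron metabolism solves may be distributed over
    ``workers`` processes.
    """
    c = c or CouplingConstants()
    if mode not in ("coupled", "fixed_atp"):
        raise ValueError(f"unknown mode {mode!r}")
    times = sync_schedule(T, c)
    n = len(population)
    if n == 0:
        raise ValueError("population is empty")

    eparams = _ParamArrays([nr.eparams for nr in population])
    states0 = [nr.initial_ephys_state() for nr in population]
    if mode == "fixed_atp":
        for s in states0:
            s.atp = c.fixed_atp_value
            s.adp = adp_from_atp(c.fixed_atp_value, c)
    sa = _StateArrays(states0)
    met_states = [nr.initial_met_state() for nr in population]
    ou_mean = np.array([nr.stim.mean for nr in population])
    ou_tau = np.array([nr.stim.tau for nr in population])
    ou_amp = np.array([nr.stim.amplitude for nr in population])
    sa.ou_value = ou_mean.copy()

    rngs = [np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=(int(nr.id),))))
        for nr in population]
    ids = [nr.id for nr in population]

    produced = np.zeros(n)
    met_sink = np.zeros(n)
    sync_clamp = np.zeros(n)
    initial_atp = sa.atp.copy()
    all_spikes: List[List[float]] = [[] for _ in range(n)]
    trace_chunks: List[Dict[str, np.ndarray]] = []
    t_chunks: List[np.ndarray] = []
    records: List[CouplingRecord] = [] if mode == "coupled" else None
    events: List[SanityEvent] = []

    pool = None
    if workers > 1 and mode == "coupled":
        import concurrent.futures as _cf
        pool = _cf.ProcessPoolExecutor(max_workers=workers)

    # initial sample at t=0
    t_chunks.append(np.array([0.0]))
    trace_chunks.append({k: getattr(sa, k).copy()[None, :]
                         for k in ("v", "na_i", "k_i", "atp", "atp_consumed_cum")})

    try:
        t_prev = 0.0
        for j, t_sync in enumerate(times, start=1):
            atp_prev = sa.atp.copy()
            seg = run_batch_segment(
                sa, eparams, ou_mean, ou_tau, ou_amp,
                duration=t_sync - t_prev, dt=c.dt_ephys, rngs=rngs,
                t0=t_prev, record_stride=record_stride,
                fixed_atp=(c.fixed_atp_value if mode == "fixed_atp" else None),
                neuron_ids=ids,
            )
            for i in range(n):
                all_spikes[i].extend(seg["spikes"][i])
            t_chunks.append(seg["t"])
            trace_chunks.append(seg["traces"])

            if mode == "coupled":
                atp_ephys = sa.atp.copy()
                tasks = []
                for i, nr in enumerate(population):
                    ms = met_states[i]
                    ms.atp_n = atp_prev[i]
                    tasks.append((ms, nr.met_params, t_sync - t_prev))
                if pool is not None:
                    results = list(pool.map(_metabolism_task, tasks, chunksize=16))
                else:
                    results = [_metabolism_task(task) for task in tasks]
                atp_met = np.empty(n)
                for i, (fs, prod, sink, _cl) in enumerate(results):
                    met_states[i] = fs
                    atp_met[i] = fs.atp_n
                    produced[i] += prod
                    met_sink[i] += sink
                merged, adjust = sync_atp(atp_prev, atp_ephys, atp_met, c)
                # pool cap: the value injected into the simulators may not
                # exceed the total adenine concentration
                capped = np.minimum(merged, c.a_tot)
                adjust = adjust + (capped - merged)
                merged = capped
                sync_clamp += adjust
                adp = adp_from_atp(np.maximum(merged, c.atp_epsilon), c)
                sa.atp = merged.copy()
                sa.adp = adp.copy()
                for i in range(n):
                    met_states[i].atp_n = merged[i]
                records.append(CouplingRecord(
                    j=j, t=t_sync, atp_prev=atp_prev, atp_ephys=atp_ephys,
                    atp_met=atp_met, atp_merged=merged, adp_merged=adp,
                    n_clamped=int(np.count_nonzero(adjust))))

            for i in range(n):
                st = {"v": sa.v[i], "na_i": sa.na_i[i], "k_i": sa.k_i[i],
                      "atp": sa.atp[i], "adp": sa.adp[i],
                      "ca_i": sa.ca_i[i], "cl_i": sa.cl_i[i]}
                events.extend(sanity_check(st, c.bounds, neuron_id=ids[i], t=t_sync))
            t_prev = t_sync
    finally:
        if pool is not None:
            pool.shutdown()

    t_all = np.concatenate(t_chunks)
    traces = {k: np.concatenate([ch[k] if ch[k].ndim == 2 else ch[k]
                                 for ch in trace_chunks], axis=0)
              for k in trace_chunks[0]}

    energy = {
        "initial_atp": initial_atp,
        "final_atp": sa.atp.copy(),
        "atp_produced": produced.copy(),
        "atp_consumed": sa.atp_consumed_cum.copy(),
        "atp_met_sink": met_sink.copy(),
        "clamp_adjust": sa.clamp_adjust + sync_clamp,
    }
    meta = {
        "mode": mode,
        "seed": int(seed),
        "T": float(T),
        "t_coupling": c.t_coupling,
        "dt_ephys": c.dt_ephys,
        "n_neurons": n,
        "neuron_ids": [int(i) for i in ids],
        "layers": [int(nr.layer) for nr in population],
        "etypes": [str(nr.etype) for nr in population],
        "areas": [float(nr.eparams.area) for nr in population],
        "n_sync": len(times),
    }
    final_ephys = {k: getattr(sa, k).copy()
                   for k in ("v", "na_i", "k_i", "ca_i", "cl_i", "atp", "adp")}
    return SimulationResult(
        t=t_all, traces=traces,
        spikes=[np.array(s) for s in all_spikes],
        coupling=records, energy=energy, sanity_events=events, meta=meta,
        final_ephys=final_ephys,
        final_met_states=met_states if mode == "coupled" else None,
    )
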