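"""Electrophysiological feature extraction and energy analyses.

Implements spike detection, the four electrical features (spike count,
maximum voltage, action-potential amplitude, resting potential), the
AP-versus-rest ATP consumption comparison, supply-demand correlations,
layer/e-type group statistics (Shapiro-Wilk + Dunn/Bonferroni), surface-area
correlations, Young/Aged condition comparison, and physiological-range
validation.

Feature definitions (pinned so results are comparable across runs):

* resting potential  - mean voltage over the final 100 ms of the last
  spike-free window (>= 20 ms away from any spike);
* AP amplitude       - mean over spikes of (peak voltage within 3 ms after
  threshold crossing) - (detection threshold, -20 mV);
* maximum voltage    - global maximum of the recorded trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import mm_to_molecules
from .coupling import SimulationResult
from .stats import dunn_test, shapiro_by_group

__all__ = [
    "SpikeTrain",
    "FeatureSet",
    "EnergyAccount",
    "detect_spikes",
    "extract_features",
    "feature_table",
    "ap_vs_rest_consumption",
    "energy_accounts",
    "supply_demand_correlation",
    "group_stats",
    "surface_feature_correlation",
    "compare_conditions",
    "validate_physiology",
    "DEFAULT_PHYS_RANGES",
]

SPIKE_THRESHOLD = -20.0  # mV
SPIKE_REFRACTORY = 2.0  # ms


@dataclass
class SpikeTrain:
    neuron_id: int
    times: np.ndarray  # ms, strictly increasing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1:
            d = np.diff(self.times)
            if np.any(d <= 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.times.size)


@dataclass
class FeatureSet:
    spike_count: int
    max_voltage: float
    ap_amplitude: float  # nan when no spikes
    resting_potential: float


@dataclass
class EnergyAccount:
    """Per-neuron ATP ledger over a run (all in mM of the neuronal pool).

    ``atp_consumed`` is the Na+/K+ pump consumption (the quantity compared
    against production in supply-demand analyses); ``atp_met_sink`` collects
    the metabolism-side sinks (housekeeping ATPase + net creatine-kinase
    storage) so the closure identity

        final = initial + produced - consumed - met_sink + clamp_adjust

    holds exactly.
    """

    neuron_id: int
    atp_produced: float
    atp_consumed: float
    atp_met_sink: float
    initial_atp: float
    final_atp: float
    clamp_adjust: float

    def closure_residual(self) -> float:
        return (self.final_atp - self.initial_atp - self.atp_produced
                + self.atp_consumed + self.atp_met_sink - self.clamp_adjust)


# ---------------------------------------------------------------------------
# spikes and features
# ---------------------------------------------------------------------------


def detect_spikes(t, v, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = SPIKE_REFRACTORY,
                  neuron_id: int = 0) -> SpikeTrain:
    """Upward threshold crossings outside the refractory window.

    ``t`` must be uniformly sampled; an empty trace yields an empty train.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size == 0:
        return SpikeTrain(neuron_id, np.empty(0))
    if t.size > 2:
        dts = np.diff(t)
        if np.max(dts) - np.min(dts) > 1e-6 * np.median(dts):
            raise ValueError("trace must be uniformly sampled")
    up = np.nonzero((v[1:] >= threshold) & (v[:-1] < threshold))[0] + 1
    times: List[float] = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refractory:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(neuron_id, np.array(times))


def extract_features(t, v, spikes: Optional[SpikeTrain] = None,
                     rest_window: float = 100.0,
                     rest_margin: float = 20.0,
                     threshold: float = SPIKE_THRESHOLD) -> FeatureSet:
    """Compute the four electrical features from a voltage trace."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if spikes is None:
        spikes = detect_spikes(t, v, threshold=threshold)
    sp = spikes.times
    max_v = float(np.max(v)) if v.size else float("nan")

    if sp.size == 0:
        amp = float("nan")
    else:
        peaks = []
        for s in sp:
            m = (t >= s) & (t <= s + 3.0)
            if m.any():
                peaks.append(np.max(v[m]))
        amp = float(np.mean(peaks) - threshold) if peaks else float("nan")

    # resting potential: final rest_window of the last spike-free stretch
    quiet = np.ones(t.size, dtype=bool)
    for s in sp:
        quiet &= (t < s - rest_margin) | (t > s + rest_margin)
    rest = float("nan")
    if quiet.any():
        # find the last contiguous quiet stretch of at least rest_window
        idx = np.nonzero(quiet)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        segments = np.split(idx, breaks + 1)
        for seg in reversed(segments):
            if t[seg[-1]] - t[seg[0]] >= rest_window:
                sel = seg[t[seg] >= t[seg[-1]] - rest_window]
                rest = float(np.mean(v[sel]))
                break
        else:
            seg = segments[-1]
            rest = float(np.mean(v[seg]))
    return FeatureSet(spike_count=int(sp.size), max_voltage=max_v,
                      ap_amplitude=amp, resting_potential=rest)


def feature_table(result: SimulationResult) -> pd.DataFrame:
    """Per-neuron feature table (with layer/e-type/area metadata)."""
    rows = []
    t = result.t
    for i in range(result.n_neurons):
        fs = extract_features(t, result.traces["v"][:, i],
                              SpikeTrain(i, result.spikes[i]))
        rows.append({
            "neuron_id": result.meta["neuron_ids"][i],
            "layer": result.meta["layers"][i],
            "etype": result.meta["etypes"][i],
            "area_um2": result.meta["areas"][i],
            "spike_count": fs.spike_count,
            "max_voltage": fs.max_voltage,
            "ap_amplitude": fs.ap_amplitude,
            "resting_potential": fs.resting_potential,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# energy analyses
# ---------------------------------------------------------------------------


def ap_vs_rest_consumption(
    t,
    atp_consumed_cum,
    spikes,
    window_ap: float = 5.0,
    window_rest: float = 25.0,
    volume_um3: Optional[float] = None,
) -> Dict[str, float]:
    """Ratio of ATP consumption rate around action potentials to the rate in
    spike-free rest windows.

    AP windows are ``window_ap`` ms centred on each spike; rest samples are
    those at least ``window_rest`` ms from every spike.  Returns a dict with
    the rate ratio, both rates (mM/ms) and, when a volume is given, absolute
    molecule counts per AP window and per second at rest.  The ratio is NaN
    (reported, not raised) when either window is empty or consumption is
    zero.
    """
    t = np.asarray(t, dtype=float)
    cum = np.asarray(atp_consumed_cum, dtype=float)
    sp = np.asarray(spikes, dtype=float)
    if t.size < 3:
        return {"ratio": float("nan"), "rate_ap": float("nan"),
                "rate_rest": float("nan"), "n_spikes": int(sp.size)}
    mid = 0.5 * (t[1:] + t[:-1])
    rate = np.diff(cum) / np.diff(t)
    ap = np.zeros(mid.size, dtype=bool)
    far = np.ones(mid.size, dtype=bool)
    for s in sp:
        ap |= np.abs(mid - s) <= window_ap / 2.0
        far &= np.abs(mid - s) >= window_rest
    out: Dict[str, float] = {"n_spikes": int(sp.size)}
    rate_ap = float(np.mean(rate[ap])) if ap.any() else float("nan")
    rate_rest = float(np.mean(rate[far])) if far.any() else float("nan")
    out["rate_ap"] = rate_ap
    out["rate_rest"] = rate_rest
    out["ratio"] = rate_ap / rate_rest if rate_rest and np.isfinite(rate_rest) \
        and rate_rest > 0 and np.isfinite(rate_ap) else float("nan")
    if volume_um3 is not None:
        out["molecules_per_ap_window"] = mm_to_molecules(
            rate_ap * window_ap, volume_um3) if np.isfinite(rate_ap) else float("nan")
        out["molecules_per_s_rest"] = mm_to_molecules(
            rate_rest * 1000.0, volume_um3) if np.isfinite(rate_rest) else float("nan")
    return out


def energy_accounts(result: SimulationResult) -> List[EnergyAccount]:
    e = result.energy
    return [EnergyAccount(
        neuron_id=result.meta["neuron_ids"][i],
        atp_produced=float(e["atp_produced"][i]),
        atp_consumed=float(e["atp_consumed"][i]),
        atp_met_sink=float(e["atp_met_sink"][i]),
        initial_atp=float(e["initial_atp"][i]),
        final_atp=float(e["final_atp"][i]),
        clamp_adjust=float(e["clamp_adjust"][i]),
    ) for i in range(result.n_neurons)]


def supply_demand_correlation(
    accounts: Sequence[EnergyAccount],
    groups: Sequence,
    spike_counts: Optional[Sequence[int]] = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-group Pearson r of ATP produced vs consumed, plus Spearman rho of
    production vs spike count when spike counts are given.

    Degenerate (zero-variance) groups are flagged with NaN correlations.
    """
    df = pd.DataFrame({
        "produced": [a.atp_produced for a in accounts],
        "consumed": [a.atp_consumed for a in accounts],
        "group": list(groups),
    })
    if spike_counts is not None:
        df["spikes"] = list(spike_counts)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        row = {"group": g, "n": len(sub), "pearson_r": np.nan,
               "spearman_rho": np.nan, "note": ""}
        if len(sub) < min_n:
            row["note"] = f"skipped (n < {min_n})"
        elif sub["produced"].std() == 0 or sub["consumed"].std() == 0:
            row["note"] = "degenerate (zero variance)"
        else:
            row["pearson_r"] = float(sps.pearsonr(sub["produced"],
                                                  sub["consumed"]).statistic)
            if "spikes" in sub and sub["spikes"].std() > 0:
                row["spearman_rho"] = float(sps.spearmanr(
                    sub["produced"], sub["spikes"]).statistic)
        rows.append(row)
    return pd.DataFrame(rows)


def group_stats(values: Sequence[float], groups: Sequence,
                min_n: int = 3) -> Dict[str, pd.DataFrame]:
    """Normality screening plus Dunn/Bonferroni pairwise comparisons."""
    return {
        "shapiro": shapiro_by_group(values, groups, min_n=min_n),
        "dunn": dunn_test(values, groups, min_n=min_n),
    }


def surface_feature_correlation(
    features: pd.DataFrame,
    feature_names: Sequence[str] = ("spike_count", "max_voltage",
                                    "ap_amplitude", "resting_potential"),
    min_n: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of surface area with each electrical feature per
    (layer, e-type) group, filtered to groups with at least ``min_n``
    complete samples and p below ``alpha``."""
    rows = []
    for (layer, etype), sub in features.groupby(["layer", "etype"], sort=True):
        for feat in feature_names:
            ok = sub[["area_um2", feat]].dropna()
            if len(ok) < min_n:
                continue
            if ok["area_um2"].std() == 0 or ok[feat].std() == 0:
                continue
            res = sps.pearsonr(ok["area_um2"], ok[feat])
            if res.pvalue < alpha:
                rows.append({"layer": layer, "etype": etype, "feature": feat,
                             "n": len(ok), "pearson_r": float(res.statistic),
                             "p": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["layer", "etype", "feature", "n",
                                       "pearson_r", "p"])


# ---------------------------------------------------------------------------
# Young vs Aged
# ---------------------------------------------------------------------------


def _match_spikes(young: np.ndarray, aged: np.ndarray, tol: float = 5.0
                  ) -> Tuple[int, int]:
    """Greedy nearest-time pairing; returns (aged_only, young_only) counts."""
    used = np.zeros(aged.size, dtype=bool)
    young_only = 0
    for ty in young:
        if aged.size:
            d = np.abs(aged - ty)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= tol:
                used[j] = True
                continue
        young_only += 1
    aged_only = int(aged.size - used.sum())
    return aged_only, young_only


def compare_conditions(young: SimulationResult, aged: SimulationResult,
                       match_tol: float = 5.0) -> Dict[str, pd.DataFrame]:
    """Paired Young/Aged comparison (same population and seeds required).

    Returns per-layer mean final-ATP differences (Young - Aged) and
    per-(layer, e-type) spike-difference counts: spikes present in Aged but
    unmatched in Young count positive, Young-only spikes negative.
    """
    for key in ("neuron_ids", "layers", "etypes"):
        if list(young.meta[key]) != list(aged.meta[key]):
            raise ValueError(f"populations differ ({key}); paired design required")
    if young.meta["seed"] != aged.meta["seed"]:
        raise ValueError("Young and Aged runs must share the stimulus seed")

    layers = np.asarray(young.meta["layers"])
    etypes = np.asarray(young.meta["etypes"])
    datp = young.energy["final_atp"] - aged.energy["final_atp"]
    atp_rows = []
    for ly in sorted(set(layers.tolist())):
        m = layers == ly
        atp_rows.append({
            "layer": ly, "n": int(m.sum()),
            "mean_final_atp_young": float(np.mean(young.energy["final_atp"][m])),
            "mean_final_atp_aged": float(np.mean(aged.energy["final_atp"][m])),
            "mean_diff_young_minus_aged": float(np.mean(datp[m])),
        })

    sp_rows = []
    for i in range(young.n_neurons):
        aged_only, young_only = _match_spikes(
            young.spikes[i], aged.spikes[i], tol=match_tol)
        sp_rows.append({"layer": int(layers[i]), "etype": str(etypes[i]),
                        "aged_only": aged_only, "young_only": young_only})
    sp = pd.DataFrame(sp_rows).groupby(["layer", "etype"], sort=True).sum()
    sp["net_diff"] = sp["aged_only"] - sp["young_only"]
    return {"atp_by_layer": pd.DataFrame(atp_rows), "spike_diff": sp.reset_index()}


# ---------------------------------------------------------------------------
# physiological validation
# ---------------------------------------------------------------------------

#: acceptance bands for end-of-run concentrations (mM) and rates (Hz);
#: configurable defaults drawn from the validation literature
DEFAULT_PHYS_RANGES: Dict[str, Tuple[float, float]] = {
    "atp": (0.5, 1.44),
    "adp": (0.0, 0.30),
    "na_i": (4.0, 30.0),
    "k_i": (100.0, 160.0),
    "ca_i": (0.0, 0.005),
    "cl_i": (2.0, 20.0),
    "rate_exc_hz": (0.0, 20.0),
    "rate_inh_hz": (0.0, 30.0),
}


def validate_physiology(result: SimulationResult,
                        ranges: Optional[Dict[str, Tuple[float, float]]] = None
                        ) -> pd.DataFrame:
    """Check end-of-run species means and firing rates against bands.

    One row per checked quantity with the population mean, the band, the
    number of individually out-of-range neurons, and a pass flag for the
    mean.
    """
    ranges = dict(DEFAULT_PHYS_RANGES if ranges is None else ranges)
    rows = []
    T = float(result.meta["T"])
    exc = np.array([e == "cADpyr" for e in result.meta["etypes"]])
    rates = result.spike_counts() / (T / 1000.0)
    for species, (lo, hi) in ranges.items():
        if species == "rate_exc_hz":
            vals = rates[exc]
        elif species == "rate_inh_hz":
            vals = rates[~exc]
        elif species in result.final_ephys:
            vals = result.final_ephys[species]
        else:
            continue
        if vals.size == 0:
            continue
        mean = float(np.mean(vals))
        rows.append({
            "species": species, "lo": lo, "hi": hi, "mean": mean,
            "n": int(vals.size),
            "n_out_of_range": int(np.count_nonzero((vals < lo) | (vals > hi))),
            "mean_in_range": bool(lo <= mean <= hi),
        })
    return pd.DataFrame(rows)
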