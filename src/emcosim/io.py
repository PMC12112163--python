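"""Results container (HDF5) and CSV exports.

Layout of a results file:

    /traces/t, /traces/<name>           recorded time series (n_times x n)
    /spikes/values, /spikes/offsets     ragged per-neuron spike times
    /coupling/<field>                   per-sync arrays (absent in fixed-ATP
                                        mode)
    /energy/<field>                     per-neuron energy ledger
    /final/<species>                    end-of-run electrophysiological state
    /meta                               JSON attribute (seeds, mode, layers,
                                        config hash, sanity events)

Round-trips are lossless at stored (float64) precision.
"""

from __future__ import annotations

import json
from typing import List, Optional

import h5py
import numpy as np
import pandas as pd

from .coupling import CouplingRecord, SanityEvent, SimulationResult

__all__ = ["save_result", "load_result", "spikes_to_csv", "FormatError"]

_COUPLING_FIELDS = ("atp_prev", "atp_ephys", "atp_met", "atp_merged", "adp_merged")


class FormatError(RuntimeError):
    """The file is not a valid results container."""


def save_result(result: SimulationResult, path: str,
                config_hash: Optional[str] = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        g.create_dataset("t", data=result.t)
        for name, arr in result.traces.items():
            g.create_dataset(name, data=arr)

        values = np.concatenate([np.asarray(s, dtype=float)
                                 for s in result.spikes]) \
            if result.spikes else np.empty(0)
        offsets = np.cumsum([0] + [len(s) for s in result.spikes])
        gs = f.create_group("spikes")
        gs.create_dataset("values", data=values)
        gs.create_dataset("offsets", data=offsets)

        if result.coupling is not None:
            gc = f.create_group("coupling")
            gc.create_dataset("j", data=np.array([r.j for r in result.coupling]))
            gc.create_dataset("t", data=np.array([r.t for r in result.coupling]))
            for name in _COUPLING_FIELDS:
                gc.create_dataset(name, data=np.stack(
                    [getattr(r, name) for r in result.coupling])
                    if result.coupling else np.empty((0, 0)))
            gc.create_dataset("n_clamped", data=np.array(
                [r.n_clamped for r in result.coupling]))

        ge = f.create_group("energy")
        for name, arr in result.energy.items():
            ge.create_dataset(name, data=arr)

        gf = f.create_group("final")
        for name, arr in result.final_ephys.items():
            gf.create_dataset(name, data=arr)

        meta = dict(result.meta)
        meta["sanity_events"] = [
            {"neuron_id": e.neuron_id, "species": e.species, "value": e.value,
             "bound": list(e.bound), "t": e.t} for e in result.sanity_events]
        if config_hash is not None:
            meta["config_hash"] = config_hash
        f.attrs["meta"] = json.dumps(meta)
        f.attrs["format"] = "emcosim-result-v1"


def load_result(path: str) -> SimulationResult:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open {path!r}: {exc}") from exc
    with f:
        if f.attrs.get("format") != "emcosim-result-v1":
            raise FormatError(f"{path!r} is not an emcosim results container")
        t = f["traces/t"][()]
        traces = {k: f["traces"][k][()] for k in f["traces"] if k != "t"}
        values = f["spikes/values"][()]
        offsets = f["spikes/offsets"][()]
        spikes = [values[offsets[i]:offsets[i + 1]]
                  for i in range(len(offsets) - 1)]
        coupling: Optional[List[CouplingRecord]] = None
        if "coupling" in f:
            gc = f["coupling"]
            coupling = []
            for i in range(len(gc["j"])):
                coupling.append(CouplingRecord(
                    j=int(gc["j"][i]), t=float(gc["t"][i]),
                    n_clamped=int(gc["n_clamped"][i]),
                    **{name: gc[name][i] for name in _COUPLING_FIELDS}))
        energy = {k: f["energy"][k][()] for k in f["energy"]}
        final = {k: f["final"][k][()] for k in f["final"]}
        meta = json.loads(f.attrs["meta"])
        events = [SanityEvent(e["neuron_id"], e["species"], e["value"],
                              tuple(e["bound"]), e["t"])
                  for e in meta.pop("sanity_events", [])]
    return SimulationResult(t=t, traces=traces, spikes=spikes,
                            coupling=coupling, energy=energy,
                            sanity_events=events, meta=meta,
                            final_ephys=final)


def spikes_to_csv(result: SimulationResult, path: str) -> pd.DataFrame:
    """Export the spike table as CSV (neuron_id, spike_time_ms)."""
    rows = []
    for i, s in enumerate(result.spikes):
        nid = result.meta["neuron_ids"][i]
        for ts in s:
            rows.append((nid, float(ts)))
    df = pd.DataFrame(rows, columns=["neuron_id", "spike_time_ms"])
    df.to_csv(path, index=False)
    return df
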