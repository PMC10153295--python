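"""CSV / JSON / HDF5 serialization for drives, spike trains, rasters, traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .jumps import DriveRealization, SpikeTrains
from .neuron import VoltageTrace
from .synchrony import SpikeRaster

__all__ = [
    "save_drive_csv", "load_drive_csv",
    "save_trains_csv", "load_trains_csv",
    "save_raster_csv", "save_trace_csv",
    "save_metadata", "save_hdf5",
]


def save_metadata(path: str | Path, meta: dict) -> None:
    """JSON sidecar with run parameters/seeds."""
    Path(path).write_text(json.dumps(meta, indent=2, default=float) + "\n")


def save_drive_csv(path: str | Path, drive: DriveRealization) -> None:
    pd.DataFrame({"t_s": drive.times, "W_e": drive.We, "W_i": drive.Wi}).to_csv(
        path, index=False
    )


def load_drive_csv(path: str | Path, T: float | None = None) -> DriveRealization:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    return DriveRealization(
        times=t,
        We=df["W_e"].to_numpy(float),
        Wi=df["W_i"].to_numpy(float),
        T=T if T is not None else (float(t[-1]) if t.size else 0.0),
    )


def save_trains_csv(path: str | Path, trains: SpikeTrains) -> None:
    pd.DataFrame({"synapse_id": trains.ids, "t_s": trains.times}).to_csv(path, index=False)


def load_trains_csv(
    path: str | Path, K: int, t_start: float, t_stop: float, population: str = "e"
) -> SpikeTrains:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    order = np.argsort(t, kind="stable")
    return SpikeTrains(
        ids=df["synapse_id"].to_numpy(np.int64)[order], times=t[order],
        K=K, population=population, t_start=t_start, t_stop=t_stop,
    )


def save_raster_csv(path: str | Path, raster: SpikeRaster) -> None:
    """Sparse triplet form: one row per spike (synapse, bin, value=1)."""
    syn, b = np.nonzero(raster.activity)
    pd.DataFrame({"synapse": syn, "bin": b, "value": np.ones_like(syn)}).to_csv(
        path, index=False
    )


def save_trace_csv(path: str | Path, trace: VoltageTrace, dt: float | None = None) -> None:
    """Uniform-grid CSV export; event-anchored traces are sampled at dt."""
    if trace.kind == "uniform_grid":
        t, v = trace.times, trace.v
    else:
        if dt is None:
            raise ValueError("dt required to grid an event-anchored trace")
        t = np.arange(trace.t_begin, trace.t_end, dt)
        v = trace.sample(t)
    pd.DataFrame({"t_s": t, "V_mV": v}).to_csv(path, index=False)


def save_hdf5(path: str | Path, **arrays) -> None:
    """Dump named arrays (raster matrices, event lists, anchored traces)
    into one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))
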