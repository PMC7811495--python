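"""HDF5 archive reader/writer for ERP datasets and simulation truth.

Layout::

    /data          float64, subjects × conditions × channels × time (μV)
    /times         float64, ms
    /channels, /conditions, /subjects   UTF-8 string arrays
    /truth/<source>   optional noise-free per-source contributions
    attrs: srate, plus free-form provenance strings
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .dataset import ErpDataset
from .simulate import SimulationResult

__all__ = ["save_dataset", "load_dataset", "save_simulation", "load_truth"]

_STR = h5py.string_dtype(encoding="utf-8")


def save_dataset(path: str | Path, data: ErpDataset, truth: dict[str, ErpDataset] | None = None,
                 provenance: dict[str, str] | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data.data)
        f.create_dataset("times", data=data.times)
        f.create_dataset("channels", data=np.asarray(data.channel_labels, dtype=_STR))
        f.create_dataset("conditions", data=np.asarray(data.condition_labels, dtype=_STR))
        f.create_dataset("subjects", data=np.asarray(data.subject_ids, dtype=_STR))
        f.attrs["srate"] = float(data.srate)
        for key, val in (provenance or {}).items():
            f.attrs[f"prov:{key}"] = str(val)
        if truth:
            g = f.create_group("truth")
            for name, ds in truth.items():
                g.create_dataset(name, data=ds.data)


def save_simulation(path: str | Path, sim: SimulationResult) -> None:
    model = sim.model
    save_dataset(path, sim.dataset, truth=sim.truth, provenance={
        "seed": model.seed,
        "snr_db": "none" if model.snr_db is None else model.snr_db,
        "latency_jitter_sd": model.latency_jitter_sd,
        "amplitude_jitter_sd": model.amplitude_jitter_sd,
    })


def _strings(arr) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in arr[()]]


def load_dataset(path: str | Path) -> ErpDataset:
    with h5py.File(path, "r") as f:
        return ErpDataset(
            data=f["data"][()],
            times=f["times"][()],
            srate=float(f.attrs["srate"]),
            channel_labels=_strings(f["channels"]),
            condition_labels=_strings(f["conditions"]),
            subject_ids=_strings(f["subjects"]),
        )


def load_truth(path: str | Path) -> dict[str, ErpDataset]:
    base = load_dataset(path)
    out: dict[str, ErpDataset] = {}
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            return out
        for name in f["truth"]:
            out[name] = ErpDataset(
                data=f["truth"][name][()], times=base.times, srate=base.srate,
                channel_labels=base.channel_labels,
                condition_labels=base.condition_labels,
                subject_ids=base.subject_ids,
            )
    return out
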