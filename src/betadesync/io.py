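"""HDF5 storage for epoched EEG and time-frequency matrices.

One file per cohort: a data cube plus JSON-encoded metadata, so a
simulation can be generated once and decomposed or re-analyzed later.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .simulate import EEGEpoch
from .tfr import TFRMatrix

__all__ = ["save_epochs", "load_epochs", "save_tfrs", "load_tfrs"]


def save_epochs(path: str | Path, epochs: list[EEGEpoch]) -> None:
    if not epochs:
        raise ValueError("no epochs to save")
    first = epochs[0]
    data = np.stack([e.data for e in epochs])
    meta = [
        {
            "participant": e.participant,
            "group": e.group,
            "condition": e.condition,
            "trial": e.trial,
        }
        for e in epochs
    ]
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data, compression="gzip")
        f.create_dataset("times", data=first.times)
        f.attrs["fs"] = first.fs
        f.attrs["channels"] = json.dumps(list(first.channels))
        f.attrs["meta"] = json.dumps(meta)


def load_epochs(path: str | Path) -> list[EEGEpoch]:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        times = f["times"][...]
        fs = float(f.attrs["fs"])
        channels = tuple(json.loads(f.attrs["channels"]))
        meta = json.loads(f.attrs["meta"])
    return [
        EEGEpoch(
            channels=channels,
            fs=fs,
            times=times.copy(),
            data=data[i],
            **meta[i],
        )
        for i in range(len(meta))
    ]


def save_tfrs(path: str | Path, tfrs: list[TFRMatrix]) -> None:
    if not tfrs:
        raise ValueError("no TFRs to save")
    first = tfrs[0]
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "power", data=np.stack([t.power for t in tfrs]), compression="gzip"
        )
        f.create_dataset("freqs", data=first.freqs)
        f.create_dataset("times", data=first.times)
        if first.valid is not None:
            f.create_dataset("valid", data=first.valid)
        f.attrs["scale"] = first.scale
        if first.baseline_window is not None:
            f.attrs["baseline_window"] = list(first.baseline_window)
        f.attrs["meta"] = json.dumps([t.meta for t in tfrs])


def load_tfrs(path: str | Path) -> list[TFRMatrix]:
    with h5py.File(path, "r") as f:
        power = f["power"][...]
        freqs = f["freqs"][...]
        times = f["times"][...]
        valid = f["valid"][...] if "valid" in f else None
        scale = str(f.attrs["scale"])
        baseline = (
            tuple(f.attrs["baseline_window"])
            if "baseline_window" in f.attrs
            else None
        )
        meta = json.loads(f.attrs["meta"])
    return [
        TFRMatrix(
            power[i],
            freqs.copy(),
            times.copy(),
            scale,
            baseline_window=baseline,
            valid=None if valid is None else valid.copy(),
            meta=meta[i],
        )
        for i in range(len(meta))
    ]
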