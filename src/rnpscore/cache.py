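"""Tensor cache: one HDF5 file per complex (datasets: data, mask, unit_order)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .featurize import ComplexTensor


def save_tensor(path: str | Path, tensor: ComplexTensor) -> None:
    with h5py.File(path, "w") as fh:
        # track_times=False keeps reruns byte-identical
        fh.create_dataset(
            "data", data=tensor.data, compression="gzip", shuffle=True,
            track_times=False,
        )
        fh.create_dataset("mask", data=tensor.mask, track_times=False)
        order = np.array(
            [f"{m}:{c}:{s}" for m, c, s in tensor.unit_order], dtype="S64"
        )
        fh.create_dataset("unit_order", data=order, track_times=False)


def load_tensor(path: str | Path) -> ComplexTensor:
    with h5py.File(path, "r") as fh:
        data = fh["data"][...]
        mask = fh["mask"][...]
        unit_order = []
        for raw in fh["unit_order"][...]:
            mol, chain, seq = raw.decode().split(":")
            unit_order.append((mol, chain, int(seq)))
    return ComplexTensor(data=data, mask=mask, unit_order=unit_order)
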