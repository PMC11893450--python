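"""File formats: MetaImage volumes, HDF5 trace containers, CSV export."""

from __future__ import annotations

import os

import h5py
import numpy as np
import SimpleITK as sitk

from .acoustic import PressureTraces
from .volume import GridSpec, Volume


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume as MetaImage (.mhd/.raw) or NIfTI, spacing/origin in mm.

    Array axis convention: ``values[ix, iy, iz]``; the file stores the same
    world geometry, so a read round-trips bitwise.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, path)


def read_volume(path: str) -> Volume:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(path)
    values = sitk.GetArrayFromImage(img).T
    grid = GridSpec(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return Volume(np.ascontiguousarray(values), grid, {"source": path})


def save_traces(traces: PressureTraces, path: str) -> None:
    """HDF5 container: /traces (channels x samples) + acquisition metadata."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("traces", data=traces.data)
        ds.attrs["sampling_mhz"] = traces.sampling_mhz
        ds.attrs["n_averages"] = traces.n_averages
        if traces.seed is not None:
            ds.attrs["seed"] = traces.seed
        meta = f.create_group("meta")
        for k, v in traces.meta.items():
            if isinstance(v, (int, float, str, np.integer, np.floating)):
                meta.attrs[k] = v


def load_traces(path: str) -> PressureTraces:
    with h5py.File(path, "r") as f:
        ds = f["traces"]
        meta = dict(f["meta"].attrs) if "meta" in f else {}
        return PressureTraces(ds[...], float(ds.attrs["sampling_mhz"]),
                              int(ds.attrs.get("n_averages", 1)),
                              int(ds.attrs["seed"]) if "seed" in ds.attrs else None,
                              meta)


def traces_to_csv(traces: PressureTraces, path: str) -> None:
    """Plain-text export for small fixtures: one column per channel."""
    header = ",".join(f"ch{i}" for i in range(traces.n_channels))
    np.savetxt(path, traces.data.T, delimiter=",", header=header, comments="")
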