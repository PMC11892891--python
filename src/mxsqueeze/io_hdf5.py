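"""HDF5 stack reader/writer (minimal NXmx-like subset).

Layout: one 3-D ``/data`` dataset of shape (n_frames, rows, cols) stored as
uint32 with gaps sentinel-substituted, plus the geometry/scan attributes on
the dataset.  This is deliberately a small documented subset, not full
NeXus compliance; the attribute names below are the contract.
"""

from __future__ import annotations

import numpy as np

import h5py

from .core import (
    DetectorGeometry,
    Frame,
    FrameStack,
    ScanMetadata,
    default_sentinel,
    mask_to_sentinel,
)

__all__ = ["write_stack_hdf5", "read_stack_hdf5", "REQUIRED_ATTRS"]

REQUIRED_ATTRS = (
    "pixel_size",
    "beam_center_row",
    "beam_center_col",
    "detector_distance",
    "wavelength",
    "osc_start",
    "osc_width",
    "count_time",
    "sentinel",
)


def write_stack_hdf5(stack: FrameStack, path, sentinel: int | None = None) -> None:
    dtype = np.uint32
    if sentinel is None:
        sentinel = default_sentinel(dtype)
    with h5py.File(path, "w") as f:
        data = np.stack([mask_to_sentinel(fr, sentinel, dtype) for fr in stack])
        ds = f.create_dataset("data", data=data, compression="gzip", shuffle=True)
        g = stack.geometry
        ds.attrs["pixel_size"] = g.pixel_size
        ds.attrs["beam_center_row"] = g.beam_center_row
        ds.attrs["beam_center_col"] = g.beam_center_col
        ds.attrs["detector_distance"] = g.detector_distance
        ds.attrs["wavelength"] = g.wavelength
        ds.attrs["gap_regions"] = np.asarray(
            [list(r) for r in g.gap_regions], dtype=np.int64
        ).reshape(-1, 4)
        s = stack.scan
        ds.attrs["osc_start"] = s.osc_start
        ds.attrs["osc_width"] = s.osc_width
        ds.attrs["count_time"] = s.count_time
        ds.attrs["sentinel"] = sentinel


def read_stack_hdf5(path) -> FrameStack:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError("missing /data dataset")
        ds = f["data"]
        for name in REQUIRED_ATTRS:
            if name not in ds.attrs:
                raise ValueError(f"{name} missing from /data attributes")
        raw = ds[...]
        sentinel = int(ds.attrs["sentinel"])
        gap_attr = np.asarray(ds.attrs.get("gap_regions", np.empty((0, 4)))).reshape(-1, 4)
        geometry = DetectorGeometry(
            n_rows=raw.shape[1],
            n_cols=raw.shape[2],
            pixel_size=float(ds.attrs["pixel_size"]),
            beam_center_row=float(ds.attrs["beam_center_row"]),
            beam_center_col=float(ds.attrs["beam_center_col"]),
            detector_distance=float(ds.attrs["detector_distance"]),
            wavelength=float(ds.attrs["wavelength"]),
            gap_regions=tuple(tuple(int(v) for v in r) for r in gap_attr),
        )
        scan = ScanMetadata(
            osc_start=float(ds.attrs["osc_start"]),
            osc_width=float(ds.attrs["osc_width"]),
            n_frames=raw.shape[0],
            count_time=float(ds.attrs["count_time"]),
        )
    frames = []
    for i in range(raw.shape[0]):
        valid = raw[i].astype(np.int64) != sentinel
        counts = np.where(valid, raw[i], 0).astype(np.int32)
        frames.append(Frame(counts, valid, i))
    return FrameStack(frames, geometry, scan)
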