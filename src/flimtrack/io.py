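"""File formats: two-channel TIFF stacks, CSV tables, JSON summaries, HDF5.

The image interchange format is a multi-frame 32-bit float TIFF with two
channels per frame - channel 1 intensity (counts), channel 2 fast lifetime
(ns) - stored as (frames, 2, rows, cols).  Undefined lifetimes are NaN; the
sidecar JSON written next to every stack records units and the sentinel so
external tools need not guess.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flim import LifetimeImage
from .movie import DecayMovie

__all__ = [
    "write_two_channel_tiff",
    "read_two_channel_tiff",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_photon_hdf5",
    "read_photon_hdf5",
]

_SIDECAR = {
    "channels": ["intensity", "lifetime"],
    "units": {"intensity": "counts", "lifetime": "ns"},
    "undefined_lifetime": "NaN",
    "axes": "TCYX",
}


def write_two_channel_tiff(stack: list[LifetimeImage], path) -> None:
    """Write a lifetime-image stack as a (frames, 2, rows, cols) float32 TIFF."""
    if not stack:
        raise ValueError("stack is empty")
    shape = stack[0].shape
    data = np.empty((len(stack), 2, *shape), dtype=np.float32)
    for i, img in enumerate(stack):
        if img.shape != shape:
            raise ValueError("inconsistent frame shapes in stack")
        data[i, 0] = img.intensity
        data[i, 1] = img.lifetime_ns
    path = Path(path)
    tifffile.imwrite(path, data, metadata={"axes": "TCYX"})
    sidecar = dict(_SIDECAR)
    sidecar["n_frames"] = len(stack)
    sidecar["frame_times_s"] = [float(img.frame_time_s) for img in stack]
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_two_channel_tiff(path) -> list[LifetimeImage]:
    """Read a two-channel stack back into LifetimeImage frames.

    Rejects single-channel or otherwise mis-shaped files with an error naming
    the expected (frames, 2, rows, cols) layout.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[0] == 2:
        data = data[None]  # single frame stored as (2, rows, cols)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError(
            f"expected a two-channel stack shaped (frames, 2, rows, cols); "
            f"got shape {data.shape} - channel 1 must be intensity, channel 2 lifetime"
        )
    times = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        times = json.loads(sidecar.read_text()).get("frame_times_s")
    return [
        LifetimeImage(
            intensity=data[i, 0].astype(np.float64),
            lifetime_ns=data[i, 1].astype(np.float64),
            frame_index=i,
            frame_time_s=float(times[i]) if times else 0.0,
        )
        for i in range(data.shape[0])
    ]


_GT_COLUMNS = ["particle", "frame", "x", "y", "in_bounds", "compartment", "tau_ns"]


def write_ground_truth_csv(ground_truth, path) -> None:
    t = ground_truth.table.copy()
    cols = [c for c in _GT_COLUMNS if c in t.columns]
    t[cols].to_csv(path, index=False, float_format="%.6f")


def read_ground_truth_csv(path, frame_shape) :
    from .scene import GroundTruth

    table = pd.read_csv(path)
    return GroundTruth(table=table, frame_shape=tuple(frame_shape))


def write_photon_hdf5(movie: DecayMovie, path) -> None:
    """Optional photon-level output: (frames, rows, cols, microtime bins)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=movie.counts, compression="gzip")
        fh.attrs["rep_rate_hz"] = movie.config.rep_rate_hz
        fh.attrs["n_microtime_bins"] = movie.config.n_microtime_bins
        fh.attrs["bin_width_ns"] = movie.config.bin_width_ns
        fh.create_dataset("frame_times_s", data=np.asarray(movie.frame_times_s))


def read_photon_hdf5(path, config) -> DecayMovie:
    import h5py

    with h5py.File(path, "r") as fh:
        counts = fh["counts"][...]
        times = fh["frame_times_s"][...]
    return DecayMovie(counts=counts, config=config, frame_times_s=times)
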