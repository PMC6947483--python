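"""Readers and writers for the pipeline's on-disk formats.

Movies are multi-page 16-bit TIFF; raw ephys is HDF5 (datasets ``/voltage``
and ``/rate_hz``) or two-column CSV (``time_s,volts``); stimulus protocols,
spike trains and traces are small CSVs; ground truth and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .ephys import EphysTrace, SpikeTrain
from .imaging import FluoTrace, Movie
from .suppression import StimulusEpoch
from .synthgen import GroundTruth

__all__ = [
    "write_movie",
    "read_movie",
    "write_ephys_h5",
    "read_ephys_h5",
    "write_ephys_csv",
    "read_ephys_csv",
    "write_epochs",
    "read_epochs",
    "write_spikes",
    "read_spikes",
    "write_trace",
    "read_trace",
    "write_ground_truth",
]


def write_movie(path: str | Path, movie: Movie) -> None:
    data = movie.pixels
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={"frame_times_s": movie.frame_times.tolist()},
    )


def read_movie(path: str | Path, frame_rate: float | None = None) -> Movie:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    ft = meta.get("frame_times_s")
    if ft is None:
        if frame_rate is None:
            raise ValueError("TIFF lacks frame times; pass frame_rate")
        ft = np.arange(1, data.shape[0] + 1) / frame_rate
    return Movie(pixels=data, frame_times=np.asarray(ft, dtype=float))


def write_ephys_h5(path: str | Path, trace: EphysTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=trace.samples)
        f.create_dataset("rate_hz", data=float(trace.rate))
        f["voltage"].attrs["t0_s"] = trace.t0


def read_ephys_h5(path: str | Path) -> EphysTrace:
    with h5py.File(path, "r") as f:
        v = f["voltage"][()]
        rate = float(f["rate_hz"][()])
        t0 = float(f["voltage"].attrs.get("t0_s", 0.0))
    return EphysTrace(samples=v, rate=rate, t0=t0)


def write_ephys_csv(path: str | Path, trace: EphysTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "volts": trace.samples}).to_csv(
        path, index=False
    )


def read_ephys_csv(path: str | Path) -> EphysTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("ephys CSV must be regularly sampled")
    return EphysTrace(samples=df["volts"].to_numpy(), rate=1.0 / dt[0], t0=float(t[0]))


def write_epochs(path: str | Path, epochs: list[StimulusEpoch]) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in epochs],
            "offset_s": [e.offset for e in epochs],
            "sign": [e.sign for e in epochs],
        }
    ).to_csv(path, index=False)


def read_epochs(path: str | Path) -> list[StimulusEpoch]:
    df = pd.read_csv(path)
    return [
        StimulusEpoch(onset=float(r.onset_s), offset=float(r.offset_s), sign=int(r.sign))
        for r in df.itertuples()
    ]


def write_spikes(path: str | Path, spikes: SpikeTrain) -> None:
    pd.DataFrame({"time_s": spikes.times}).to_csv(path, index=False)


def read_spikes(path: str | Path, source_rate: float = np.nan) -> SpikeTrain:
    df = pd.read_csv(path)
    return SpikeTrain(times=df["time_s"].to_numpy(), source_rate=source_rate)


def write_trace(path: str | Path, trace: FluoTrace) -> None:
    pd.DataFrame({"time_s": trace.frame_times, "value": trace.values}).to_csv(
        path, index=False
    )


def read_trace(path: str | Path, units: str = "counts") -> FluoTrace:
    df = pd.read_csv(path)
    return FluoTrace(
        values=df["value"].to_numpy(),
        frame_times=df["time_s"].to_numpy(),
        units=units,
        baseline_F=1.0 if units == "dff" else None,
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    payload = {}
    for name in gt.__dataclass_fields__:
        v = getattr(gt, name)
        if v is None:
            continue
        if name == "roi_masks":
            v = [{"label": m.label, "pixels": m.pixels.tolist()} for m in v]
        payload[name] = _jsonable(v)
    Path(path).write_text(json.dumps(payload))
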