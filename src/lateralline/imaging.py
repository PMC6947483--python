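"""Fluorescence movie analysis: background subtraction, correlation-seeded
ROI segmentation, trace extraction and ΔF/F normalisation.

Glutamate (iGluSnFR) or calcium (GCaMP) movies of a neuromast are acquired at
20–50 Hz.  Active synapses show up as small blobs whose pixels share a common
time course, which is what the segmentation exploits: pixels that correlate
strongly with their 8-neighbours become seeds, and each seed is grown into a
spatially contiguous ROI by adding neighbouring pixels whose time course
correlates with the ROI's running mean trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Movie",
    "RoiMask",
    "FluoTrace",
    "subtract_background",
    "neighbor_correlation_map",
    "segment_rois",
    "extract_traces",
    "compute_dff",
]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Movie:
    """An image stack (frames x height x width) with frame timestamps.

    Frame timestamps mark the END of each frame's exposure, so a frame's
    value reflects activity in its preceding frame interval.
    """

    pixels: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("movie pixels must be a (frames, height, width) array")
        if self.frame_times.size != self.pixels.shape[0]:
            raise ValueError("frame_times length must match frame count")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass
class RoiMask:
    """A set of (row, col) pixel coordinates forming one ROI (0-based)."""

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    label: int

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise ValueError("an ROI mask must contain at least one pixel")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def as_bool(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class FluoTrace:
    """A per-ROI fluorescence time series.

    ``units`` is ``"counts"`` for raw extracted traces and ``"dff"`` after
    baseline normalisation; ``baseline_F`` stores the baseline fluorescence
    used for the ΔF/F conversion.
    """

    values: np.ndarray
    frame_times: np.ndarray
    baseline_F: float | None = None
    roi_label: int | None = None
    units: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.size != self.frame_times.size:
            raise ValueError("values and frame_times must have equal length")
        if self.units == "dff" and (self.baseline_F is None or self.baseline_F <= 0):
            raise ValueError("a ΔF/F trace requires baseline_F > 0")

    @property
    def frame_rate(self) -> float:
        dts = np.diff(self.frame_times)
        return 1.0 / float(np.median(dts)) if dts.size else np.nan


def subtract_background(movie: Movie, percentile: float = 5.0) -> Movie:
    """Subtract a per-frame scalar background (a low percentile of the frame).

    Clips at zero so counts stay non-negative.  Automates the manual
    background-ROI step of a typical imaging workflow: in a sparse neuromast
    movie a low percentile of each frame is background with high probability.
    """
    if not 0.0 < percentile < 50.0:
        raise ValueError("percentile must lie in (0, 50)")
    if movie.n_frames == 0 or movie.pixels.size == 0:
        raise ValueError("empty movie")
    px = movie.pixels.astype(np.float32)
    bg = np.percentile(px, percentile, axis=(1, 2), keepdims=True).astype(np.float32)
    px -= bg
    np.maximum(px, 0.0, out=px)
    return Movie(pixels=px, frame_times=movie.frame_times.copy())


def _zscore_stack(px: np.ndarray) -> np.ndarray:
    """Per-pixel temporally z-scored stack; constant pixels map to zero."""
    px = px.astype(np.float32, copy=True)
    mu = px.mean(axis=0, dtype=np.float64).astype(np.float32)
    sd = px.std(axis=0, dtype=np.float64).astype(np.float32)
    px -= mu
    sd_safe = np.where(sd > 0, sd, np.float32(1.0))
    px /= sd_safe
    px[:, sd == 0] = 0.0
    return px


def _neighbor_correlation_from_z(z: np.ndarray) -> np.ndarray:
    nt, h, w = z.shape
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for dr, dc in _NEIGHBORS8:
        r0, r1 = max(0, dr), h + min(0, dr)
        c0, c1 = max(0, dc), w + min(0, dc)
        prod = (z[:, r0:r1, c0:c1] * z[:, r0 - dr : r1 - dr, c0 - dc : c1 - dc]).mean(
            axis=0
        )
        acc[r0:r1, c0:c1] += prod
        cnt[r0:r1, c0:c1] += 1
    return acc / cnt


def neighbor_correlation_map(movie: Movie) -> np.ndarray:
    """Mean Pearson correlation of each pixel's time course with its
    8-neighbours.  Constant (degenerate) pixels get correlation 0."""
    return _neighbor_correlation_from_z(_zscore_stack(movie.pixels))


def segment_rois(
    movie: Movie,
    seed_quantile: float = 0.95,
    grow_threshold: float = 0.5,
    min_size: int = 4,
    max_size: int = 400,
) -> list[RoiMask]:
    """Correlation-seeded region growing.

    Pixels whose neighbour-correlation exceeds the ``seed_quantile`` of the
    map become seeds, visited best first.  Each unclaimed seed is grown by
    breadth-first addition of 8-connected pixels whose time course correlates
    with the ROI's mean trace at ``grow_threshold`` or better.  Pixels are
    claimed by at most one ROI; regions smaller than ``min_size`` pixels are
    discarded as speckle.
    """
    if movie.n_frames < 10:
        raise ValueError("need at least 10 frames to segment")
    if not (0.0 < seed_quantile < 1.0 and 0.0 < grow_threshold < 1.0):
        raise ValueError("seed_quantile and grow_threshold must lie in (0, 1)")
    px = movie.pixels
    nt, h, w = px.shape
    z = _zscore_stack(px)
    cmap = _neighbor_correlation_from_z(z)
    thr = np.quantile(cmap, seed_quantile)
    seed_rc = np.argwhere(cmap > thr)
    order = np.argsort(cmap[seed_rc[:, 0], seed_rc[:, 1]])[::-1]
    seed_rc = seed_rc[order]

    claimed = np.zeros((h, w), dtype=bool)
    masks: list[RoiMask] = []
    for sr, sc in seed_rc:
        if claimed[sr, sc]:
            continue
        region = [(int(sr), int(sc))]
        trace_sum = px[:, sr, sc].astype(np.float64)
        in_region = {(int(sr), int(sc))}
        visited = set(in_region)
        frontier = [
            (sr + dr, sc + dc)
            for dr, dc in _NEIGHBORS8
            if 0 <= sr + dr < h and 0 <= sc + dc < w
        ]
        while frontier and len(region) < max_size:
            r, c = frontier.pop(0)
            if (r, c) in visited or claimed[r, c]:
                continue
            visited.add((r, c))
            mean_trace = trace_sum / len(region)
            sd = mean_trace.std()
            if sd == 0:
                continue
            mz = (mean_trace - mean_trace.mean()) / sd
            r_pix = float(np.dot(z[:, r, c], mz) / nt)
            if r_pix >= grow_threshold:
                region.append((r, c))
                in_region.add((r, c))
                trace_sum += px[:, r, c]
                for dr, dc in _NEIGHBORS8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and (rr, cc) not in visited:
                        frontier.append((rr, cc))
        if len(region) >= min_size:
            coords = np.asarray(region, dtype=int)
            claimed[coords[:, 0], coords[:, 1]] = True
            masks.append(RoiMask(pixels=coords, label=len(masks) + 1))
    return masks


def extract_traces(movie: Movie, masks: list[RoiMask]) -> list[FluoTrace]:
    """Per-frame mean over each mask's pixels, in raw counts."""
    h, w = movie.shape
    traces = []
    for m in masks:
        if np.any(m.pixels < 0) or np.any(m.pixels[:, 0] >= h) or np.any(
            m.pixels[:, 1] >= w
        ):
            raise ValueError(f"mask {m.label} has out-of-bounds pixels")
        vals = movie.pixels[:, m.pixels[:, 0], m.pixels[:, 1]].astype(float).mean(axis=1)
        traces.append(
            FluoTrace(
                values=vals,
                frame_times=movie.frame_times.copy(),
                roi_label=m.label,
                units="counts",
            )
        )
    return traces


def compute_dff(
    trace: FluoTrace,
    first_stim_onset: float | None = None,
    baseline_window: float = 10.0,
) -> FluoTrace:
    """Normalise a raw trace to ΔF/F.

    Baseline fluorescence F is the mean over the first ``baseline_window``
    seconds of imaging, truncated at the first stimulus onset so no evoked
    response leaks into the baseline.
    """
    t = trace.frame_times
    t_end = t[0] + baseline_window
    if first_stim_onset is not None:
        t_end = min(t_end, first_stim_onset)
    sel = t < t_end
    if not np.any(sel):
        raise ValueError("no frames in the baseline window")
    f0 = float(trace.values[sel].mean())
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence must be positive, got {f0}")
    return FluoTrace(
        values=(trace.values - f0) / f0,
        frame_times=t.copy(),
        baseline_F=f0,
        roi_label=trace.roi_label,
        units="dff",
    )
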