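"""Motor-nerve electrophysiology: filtering, spike detection, rates and bouts.

The posterior lateral-line preparation yields an extracellular voltage trace
from the motor nerve sampled at 5 kHz.  Fictive swimming appears as discrete
bursts ("bouts") of spikes separated by seconds of quiescence.  This module
converts the raw voltage into a band-passed trace, a spike train, a smoothed
firing-rate series and a list of bouts, and provides the frame-aligned spike
counts used by the imaging-side analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "EphysTrace",
    "SpikeTrain",
    "Bout",
    "RateSeries",
    "filter_motor_trace",
    "detect_spikes",
    "spike_rate",
    "segment_bouts",
    "downsample_to_frames",
]

#: MAD -> SD conversion for Gaussian noise.
MAD_SCALE = 1.4826


@dataclass
class EphysTrace:
    """A voltage trace sampled at a fixed rate.

    Parameters
    ----------
    samples
        Voltage samples (volts).
    rate
        Sampling rate in samples/s.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) with the sampling rate they were detected at."""

    times: np.ndarray
    source_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Bout:
    """A swim bout: a run of spikes with short inter-spike intervals."""

    start: float
    end: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.n_spikes < 1:
            raise ValueError("a bout contains at least one spike")
        if self.end < self.start:
            raise ValueError("bout end precedes start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RateSeries:
    """A firing-rate time series (spikes/s) on a regular grid."""

    times: np.ndarray
    values: np.ndarray


def filter_motor_trace(
    trace: EphysTrace,
    band: tuple[float, float] = (300.0, 1000.0),
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    order: int = 2,
) -> EphysTrace:
    """Band-pass (default 300–1000 Hz) plus mains-notch filter, zero phase.

    Both stages run forward and backward (``filtfilt``) so no latency is
    introduced; the downstream lag estimates rely on this.

    Raises
    ------
    ValueError
        If the sampling rate is below 2.5 kHz (Nyquist margin for the
        1 kHz corner).
    """
    lo, hi = band
    if trace.rate < 2.5 * hi:
        raise ValueError(
            f"sampling rate {trace.rate} samples/s too low for a {hi} Hz corner"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.rate, output="sos")
    x = signal.sosfiltfilt(sos, trace.samples)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=trace.rate)
    x = signal.filtfilt(b, a, x)
    return EphysTrace(samples=x, rate=trace.rate, t0=trace.t0)


def detect_spikes(
    trace: EphysTrace,
    threshold_mads: float = 5.0,
    polarity: str = "abs",
    refractory: float = 0.002,
) -> SpikeTrain:
    """Threshold crossings of the filtered trace.

    The threshold is ``threshold_mads`` times a robust noise scale
    (median absolute deviation x 1.4826).  One spike is recorded per upward
    crossing; crossings closer together than ``refractory`` (default 2 ms)
    are merged into the first.

    Parameters
    ----------
    polarity
        ``"abs"`` (default) detects on the rectified trace, ``"pos"`` /
        ``"neg"`` on the raw or inverted trace (extracellular spikes may be
        negative-going).
    """
    x = trace.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if polarity == "abs":
        y = np.abs(x)
    elif polarity == "pos":
        y = x
    elif polarity == "neg":
        y = -x
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    mad = np.median(np.abs(x - np.median(x)))
    thr = threshold_mads * MAD_SCALE * mad
    if thr <= 0:
        # flat trace: no noise scale, no spikes
        return SpikeTrain(times=np.empty(0), source_rate=trace.rate)
    above = y >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    if crossings.size:
        keep = [crossings[0]]
        min_gap = refractory * trace.rate
        for c in crossings[1:]:
            if c - keep[-1] >= min_gap:
                keep.append(c)
        crossings = np.asarray(keep)
    times = trace.t0 + crossings / trace.rate
    return SpikeTrain(times=times, source_rate=trace.rate)


def spike_rate(
    spikes: SpikeTrain,
    fwhm: float = 0.1,
    grid_rate: float = 100.0,
    t_start: float | None = None,
    t_stop: float | None = None,
) -> RateSeries:
    """Smoothed firing rate: sum of unit-area Gaussians at the spike times.

    The smoothing kernel is a Gaussian with the given full width at half
    maximum (default 100 ms, sigma = fwhm / 2.3548).  The integral of the
    returned series equals the spike count, up to edge truncation.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if t_start is None:
        t_start = (spikes.times[0] - 5 * sigma) if len(spikes) else 0.0
    if t_stop is None:
        t_stop = (spikes.times[-1] + 5 * sigma) if len(spikes) else 1.0
    t = np.arange(t_start, t_stop, 1.0 / grid_rate)
    values = np.zeros_like(t)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    half = 6.0 * sigma
    for s in spikes.times:
        i0, i1 = np.searchsorted(t, [s - half, s + half])
        seg = t[i0:i1]
        values[i0:i1] += norm * np.exp(-0.5 * ((seg - s) / sigma) ** 2)
    return RateSeries(times=t, values=values)


def segment_bouts(spikes: SpikeTrain, max_isi: float = 0.2) -> list[Bout]:
    """Group spikes into bouts: maximal runs with consecutive gaps <= max_isi.

    Bout start/end are the first/last spike times of the run.
    """
    if max_isi <= 0:
        raise ValueError("max_isi must be positive")
    t = spikes.times
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > max_isi) + 1
    bouts = []
    for run in np.split(t, breaks):
        bouts.append(Bout(start=float(run[0]), end=float(run[-1]), n_spikes=run.size))
    return bouts


def downsample_to_frames(spikes: SpikeTrain, frame_times: np.ndarray) -> np.ndarray:
    """Per-frame spike counts at the imaging frame rate.

    Frame timestamps mark the end of each frame's exposure; frame *k* counts
    the spikes in the half-open interval ``(t_{k-1}, t_k]``, so a spike
    falling exactly on a timestamp belongs to that frame.  The first frame's
    interval extends one median frame period before ``frame_times[0]``.
    """
    ft = np.asarray(frame_times, dtype=float)
    if ft.size == 0:
        return np.zeros(0, dtype=int)
    if np.any(np.diff(ft) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    dt = np.median(np.diff(ft)) if ft.size > 1 else 1.0
    edges = np.concatenate([[ft[0] - dt], ft])
    right = np.searchsorted(spikes.times, edges, side="right")
    return np.diff(right).astype(int)
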