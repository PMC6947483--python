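"""Motor-to-sensory coupling statistics.

Two quantifications link the motor-nerve spike train to fluorescence:

* per-bout signal integrals versus spike counts (positive slope for the
  efferent calcium signal, negative for suppressed glutamate release), and
* the signed cross-correlogram between a fluorescence trace and the
  frame-downsampled spike train, whose most negative value locates the
  suppression lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ephys import Bout
from .imaging import FluoTrace

__all__ = [
    "BoutMetrics",
    "XCorrResult",
    "bout_fluorescence_integral",
    "spike_count_integral_correlation",
    "cross_correlate_lag",
]


@dataclass
class BoutMetrics:
    """Spike count and signed fluorescence integral for one swim bout."""

    bout: Bout
    n_spikes: int
    fluo_integral: float  # ΔF/F * s, signed


@dataclass
class XCorrResult:
    """Normalised cross-correlogram between spike counts and fluorescence.

    Positive lags mean the fluorescence change FOLLOWS the spikes.
    ``extremum_lag`` is the lag (s) of the most negative correlation, the
    convention used for suppression analyses.
    """

    lags: np.ndarray  # seconds
    correlation: np.ndarray
    extremum_lag: float
    extremum_value: float


def bout_fluorescence_integral(
    trace: FluoTrace,
    bout: Bout,
    extension: float = 0.5,
    baseline_window: float = 0.5,
) -> BoutMetrics:
    """Trapezoidal ΔF/F integral over a bout (plus a post-bout extension).

    The integrand is referenced to the mean ΔF/F in the ``baseline_window``
    seconds preceding the bout, so a flat trace integrates to zero and
    suppression below the pre-bout level yields a negative integral.
    """
    t = trace.frame_times
    t1 = bout.end + extension
    if bout.start < t[0] - (t[1] - t[0] if t.size > 1 else 0.0) or t1 > t[-1]:
        raise ValueError("bout window extends outside the trace")
    pre = (t >= bout.start - baseline_window) & (t < bout.start)
    base = float(trace.values[pre].mean()) if np.any(pre) else 0.0
    sel = (t >= bout.start) & (t <= t1)
    if np.count_nonzero(sel) < 2:
        raise ValueError("bout window covers fewer than two frames")
    integral = float(np.trapezoid(trace.values[sel] - base, t[sel]))
    return BoutMetrics(bout=bout, n_spikes=bout.n_spikes, fluo_integral=integral)


def spike_count_integral_correlation(metrics: list[BoutMetrics]) -> float:
    """Pearson correlation between per-bout spike counts and integrals."""
    if len(metrics) < 3:
        raise ValueError("need at least 3 bouts")
    n = np.asarray([m.n_spikes for m in metrics], dtype=float)
    g = np.asarray([m.fluo_integral for m in metrics], dtype=float)
    if n.std() == 0 or g.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(n, g)[0, 1])


def cross_correlate_lag(
    trace: FluoTrace,
    frame_counts: np.ndarray,
    max_lag: float,
) -> XCorrResult:
    """Pearson correlation at every integer frame lag in [-max_lag, max_lag].

    Each lag's correlation is computed on the mean-subtracted overlapping
    segments (a true Pearson r per lag), so |r| <= 1 holds exactly.
    Positive lag = fluorescence shifted later than the spike counts.
    """
    y = trace.values
    x = np.asarray(frame_counts, dtype=float)
    if x.size != y.size:
        raise ValueError("trace and frame_counts must have equal length")
    dt = 1.0 / trace.frame_rate
    max_shift = int(round(max_lag / dt))
    if max_shift < 1:
        raise ValueError("max_lag must cover at least one frame")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: constant input")
    lags = np.arange(-max_shift, max_shift + 1)
    corr = np.empty(lags.size)
    n = x.size
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            corr[i] = np.nan
            continue
        corr[i] = np.corrcoef(a, b)[0, 1]
    imin = int(np.nanargmin(corr))
    return XCorrResult(
        lags=lags * dt,
        correlation=corr,
        extremum_lag=float(lags[imin] * dt),
        extremum_value=float(corr[imin]),
    )
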