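"""Suppression-index statistics for efference-copy inhibition.

The suppression index compares, frame by frame during a mechanical stimulus,
one trial's response R_m(t) with the mean response R_o(t) of trials without
motor activity:

    SI(t) = (R_o(t) - R_m(t)) / R_o(t)

SI = 0 means no suppression, SI = 1 full suppression of the evoked response,
and SI > 1 suppression below the pre-stimulus baseline (spontaneous release
blocked as well).  Pooled (N_s, SI) points — N_s being the motor spike count
in the 50 ms preceding each frame — follow a Hill relation

    SI(N_s) = SI_max * N_s / (N_s + N_1/2)

and each synapse is classified as suppressed or unaffected by a one-tailed
Mann-Whitney comparison of spike-coincident versus spike-free frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ephys import SpikeTrain
from .imaging import FluoTrace

__all__ = [
    "StimulusEpoch",
    "Trial",
    "TrialSet",
    "SIProfile",
    "HillFit",
    "SynapseClassification",
    "PolarityComparison",
    "build_trial_set",
    "mean_quiet_response",
    "suppression_index",
    "compute_si_profiles",
    "pool_si_vs_spikes",
    "fit_hill",
    "hill_predict",
    "classify_synapse",
    "polarity_binomial_test",
    "compare_polarity_groups",
    "synapse_mean_si",
]

#: spike-count window preceding each frame (s)
NS_WINDOW = 0.05


@dataclass(frozen=True)
class StimulusEpoch:
    """One pressure step.

    ``sign`` is +1 for a positive step (posterior deflection of the cupula)
    and -1 for a negative step (anterior deflection).
    """

    onset: float
    offset: float
    sign: int

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("epoch onset must precede offset")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Trial:
    """One stimulus presentation for one synapse."""

    epoch: StimulusEpoch
    values: np.ndarray        # ΔF/F at the in-epoch frames (first frame dropped)
    frame_times: np.ndarray
    n_s: np.ndarray           # spikes in the 50 ms window preceding each frame
    frame_counts: np.ndarray  # spikes in each frame's own preceding frame interval
    quiet: bool               # no motor spikes during (onset - 50 ms, offset]


@dataclass
class TrialSet:
    """All trials of one synapse for the epochs matching its polarity."""

    synapse_id: int | str
    polarity: str  # "posterior" or "anterior"
    trials: list[Trial]

    @property
    def quiet_trials(self) -> list[Trial]:
        return [tr for tr in self.trials if tr.quiet]

    @property
    def active_trials(self) -> list[Trial]:
        return [tr for tr in self.trials if not tr.quiet]


@dataclass
class SIProfile:
    """Per-trial suppression-index profile on the aligned stimulus frames."""

    r_o: np.ndarray
    r_m: np.ndarray
    si: np.ndarray
    n_s: np.ndarray
    valid: np.ndarray  # SI defined only where R_o clears the division guard


@dataclass
class HillFit:
    """Hill-equation fit SI(N) = si_max * N / (N + n_half)."""

    si_max: float
    n_half: float
    si_max_se: float
    n_half_se: float
    rss: float
    n_points: int


@dataclass
class SynapseClassification:
    """Outcome of the three-step suppressed/unaffected test."""

    label: str  # "suppressed" | "unaffected" | "untestable"
    u_statistic: float
    p_value: float
    n_coincident: int
    n_noncoincident: int


@dataclass
class PolarityComparison:
    """Group summary of per-synapse SI for the two hair-cell polarities."""

    mean_posterior: float
    sem_posterior: float
    mean_anterior: float
    sem_anterior: float
    p_value: float
    statistic: str
    low_n: bool  # True when either group has < 3 synapses


POLARITY_SIGN = {"posterior": 1, "anterior": -1}


def build_trial_set(
    trace: FluoTrace,
    epochs: list[StimulusEpoch],
    spikes: SpikeTrain,
    polarity: str,
    synapse_id: int | str = 0,
    ns_window: float = NS_WINDOW,
    coincidence_window: float | None = None,
) -> TrialSet:
    """Slice a ΔF/F trace into stimulus-aligned trials.

    For each epoch whose sign matches the synapse's polarity, the frames with
    timestamps in ``(onset, offset]`` are taken and the FIRST one dropped
    (its timing within the frame interval is uncertain).  Each kept frame
    gets two spike counts: ``n_s`` over the preceding ``ns_window`` (50 ms)
    and ``frame_counts`` over the frame's own preceding frame interval
    (used for the coincidence classification; identical at 20 Hz).  A trial
    is *quiet* when no spike falls in ``(onset - ns_window, offset]``.

    Trials are trimmed to a common frame count so they align frame-by-frame
    from stimulus onset.
    """
    if polarity not in POLARITY_SIGN:
        raise ValueError(f"unknown polarity {polarity!r}")
    sign = POLARITY_SIGN[polarity]
    my_epochs = [e for e in epochs if e.sign == sign]
    if not my_epochs:
        raise ValueError(f"no epochs with sign {sign} for polarity {polarity!r}")
    t = trace.frame_times
    st = spikes.times
    if coincidence_window is None:
        coincidence_window = 1.0 / trace.frame_rate
    trials = []
    for ep in my_epochs:
        sel = np.flatnonzero((t > ep.onset) & (t <= ep.offset))
        if sel.size <= 1:
            continue
        sel = sel[1:]  # drop the first in-epoch frame
        ft = t[sel]
        n_s = _window_counts(st, ft, ns_window)
        fc = _window_counts(st, ft, coincidence_window)
        n_in = np.searchsorted(st, ep.offset, side="right") - np.searchsorted(
            st, ep.onset - ns_window, side="right"
        )
        trials.append(
            Trial(
                epoch=ep,
                values=trace.values[sel].copy(),
                frame_times=ft,
                n_s=n_s,
                frame_counts=fc,
                quiet=bool(n_in == 0),
            )
        )
    if not trials:
        raise ValueError("no usable trials: epochs contain too few frames")
    n_min = min(tr.values.size for tr in trials)
    for tr in trials:
        tr.values = tr.values[:n_min]
        tr.frame_times = tr.frame_times[:n_min]
        tr.n_s = tr.n_s[:n_min]
        tr.frame_counts = tr.frame_counts[:n_min]
    return TrialSet(synapse_id=synapse_id, polarity=polarity, trials=trials)


def _window_counts(spike_times: np.ndarray, frame_times: np.ndarray, window: float) -> np.ndarray:
    """Spikes in the half-open window (t - window, t] for each frame time."""
    hi = np.searchsorted(spike_times, frame_times, side="right")
    lo = np.searchsorted(spike_times, frame_times - window, side="right")
    return (hi - lo).astype(int)


def mean_quiet_response(ts: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise mean and standard error of the quiet trials (R_o)."""
    quiet = ts.quiet_trials
    if not quiet:
        raise ValueError(
            "no quiet trials: R_o undefined, synapse is untestable"
        )
    vals = np.stack([tr.values for tr in quiet])
    mean = vals.mean(axis=0)
    sem = (
        vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0])
        if vals.shape[0] > 1
        else np.full(mean.shape, np.nan)
    )
    return mean, sem


def suppression_index(
    r_o: np.ndarray, r_m: np.ndarray, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise SI = (R_o - R_m) / R_o with a division guard.

    Frames with R_o below ``floor`` are marked invalid (SI undefined) rather
    than producing huge ratios.  Negative SI values are legitimate (response
    during motor activity larger than the quiet mean) and are kept.
    """
    r_o = np.asarray(r_o, dtype=float)
    r_m = np.asarray(r_m, dtype=float)
    if r_o.shape != r_m.shape:
        raise ValueError("R_o and R_m must have equal length")
    valid = r_o >= floor
    if not np.any(valid):
        raise ValueError("all frames fall below the R_o division guard")
    si = np.full(r_o.shape, np.nan)
    si[valid] = (r_o[valid] - r_m[valid]) / r_o[valid]
    return si, valid


def compute_si_profiles(ts: TrialSet, floor: float | None = None) -> list[SIProfile]:
    """SI profile for every trial of a synapse.

    ``floor`` defaults to 3 x the standard error of R_o (averaged over
    frames), the guard against division by a near-zero quiet response.
    """
    r_o, sem = mean_quiet_response(ts)
    if floor is None:
        s = np.nanmean(sem)
        floor = 3.0 * s if np.isfinite(s) else 0.0
    profiles = []
    for tr in ts.trials:
        si, valid = suppression_index(r_o, tr.values, floor)
        profiles.append(
            SIProfile(r_o=r_o, r_m=tr.values, si=si, n_s=tr.n_s, valid=valid)
        )
    return profiles


def pool_si_vs_spikes(profiles: list[SIProfile]) -> pd.DataFrame:
    """Pool all valid (N_s, SI) pairs and summarise per integer spike count.

    Pooling is across synapses and trials (every valid frame is one point),
    not per-synapse averages.  Returns a DataFrame indexed by ``n_s`` with
    columns ``mean``, ``sem`` and ``count``; the raw points are attached as
    ``df.attrs["points"]``.
    """
    ns_all, si_all = [], []
    for p in profiles:
        ok = p.valid & np.isfinite(p.si)
        ns_all.append(p.n_s[ok])
        si_all.append(p.si[ok])
    ns = np.concatenate(ns_all) if ns_all else np.empty(0, dtype=int)
    si = np.concatenate(si_all) if si_all else np.empty(0)
    if ns.size == 0:
        raise ValueError("no valid (N_s, SI) points to pool")
    pts = pd.DataFrame({"n_s": ns, "si": si})
    grouped = pts.groupby("n_s")["si"].agg(["mean", "sem", "count"])
    grouped.attrs["points"] = pts
    return grouped


def _hill(n: np.ndarray, si_max: float, n_half: float) -> np.ndarray:
    return si_max * n / (n + n_half)


def fit_hill(
    n_s: np.ndarray,
    si: np.ndarray,
    weights: np.ndarray | None = None,
    p0: tuple[float, float] = (1.0, 1.0),
) -> HillFit:
    """Least-squares Hill fit to (N_s, SI) points.

    Points may be the raw pooled pairs (each with weight 1, i.e. groups
    weighted by how many frames they contain) or grouped means with
    ``weights`` = 1/SEM.  Parameters are constrained to si_max >= 0,
    n_half > 0; standard errors come from the fit covariance.
    """
    n_s = np.asarray(n_s, dtype=float)
    si = np.asarray(si, dtype=float)
    if np.unique(n_s).size < 3:
        raise ValueError("need at least 3 distinct N_s values to fit")
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    try:
        popt, pcov = optimize.curve_fit(
            _hill,
            n_s,
            si,
            p0=p0,
            sigma=sigma,
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Hill fit failed to converge: {exc}") from exc
    resid = si - _hill(n_s, *popt)
    se = np.sqrt(np.diag(pcov))
    return HillFit(
        si_max=float(popt[0]),
        n_half=float(popt[1]),
        si_max_se=float(se[0]),
        n_half_se=float(se[1]),
        rss=float(np.sum(resid**2)),
        n_points=int(n_s.size),
    )


def hill_predict(fit: HillFit | tuple[float, float], n_spikes) -> np.ndarray | float:
    """Evaluate the Hill curve SI(N) = si_max * N / (N + n_half)."""
    if isinstance(fit, HillFit):
        si_max, n_half = fit.si_max, fit.n_half
    else:
        si_max, n_half = fit
    n = np.asarray(n_spikes, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_spikes must be non-negative")
    out = _hill(n, si_max, n_half)
    return float(out) if out.ndim == 0 else out


def classify_synapse(ts: TrialSet, alpha: float = 0.05) -> SynapseClassification:
    """Three-step suppressed/unaffected classification.

    1. Pool all in-stimulus frames across trials (first frames already
       dropped when the trial set was built).
    2. Partition them into frames coinciding with >= 1 motor spike in their
       preceding frame interval versus spike-free frames.
    3. One-tailed Mann-Whitney U test of coincident < spike-free; the synapse
       is *suppressed* when p < alpha, *untestable* when either partition is
       empty (e.g. no motor activity ever overlapped a stimulus).
    """
    vals = np.concatenate([tr.values for tr in ts.trials])
    coin = np.concatenate([tr.frame_counts >= 1 for tr in ts.trials])
    x = vals[coin]       # coincident with motor spikes
    y = vals[~coin]      # no motor spikes
    if x.size == 0 or y.size == 0:
        return SynapseClassification(
            label="untestable",
            u_statistic=np.nan,
            p_value=np.nan,
            n_coincident=int(x.size),
            n_noncoincident=int(y.size),
        )
    res = stats.mannwhitneyu(x, y, alternative="less", method="auto")
    label = "suppressed" if res.pvalue < alpha else "unaffected"
    return SynapseClassification(
        label=label,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_coincident=int(x.size),
        n_noncoincident=int(y.size),
    )


def polarity_binomial_test(p_overall: float, n_group: int) -> float:
    """Probability that all ``n_group`` synapses are suppressed under a
    polarity-blind null in which each is suppressed independently with
    probability ``p_overall``:  p_overall ** n_group."""
    if not 0.0 <= p_overall <= 1.0:
        raise ValueError("p_overall must lie in [0, 1]")
    if n_group < 0:
        raise ValueError("n_group must be non-negative")
    return float(p_overall**n_group)


def synapse_mean_si(
    profiles: list[SIProfile], statistic: str = "mean_si"
) -> float:
    """Per-synapse SI summary during motor activity.

    ``mean_si``: mean SI over valid frames with N_s >= 1 (frames during a
    swim bout); ``max_si``: the maximal such SI.  NaN when the synapse never
    overlapped motor activity.
    """
    vals = []
    for p in profiles:
        ok = p.valid & np.isfinite(p.si) & (p.n_s >= 1)
        vals.append(p.si[ok])
    v = np.concatenate(vals) if vals else np.empty(0)
    if v.size == 0:
        return float("nan")
    if statistic == "mean_si":
        return float(v.mean())
    if statistic == "max_si":
        return float(v.max())
    raise ValueError(f"unknown statistic {statistic!r}")


def compare_polarity_groups(
    si_posterior: list[float] | np.ndarray,
    si_anterior: list[float] | np.ndarray,
    statistic: str = "mean_si",
) -> PolarityComparison:
    """Group means ± SEM and a two-sided Mann-Whitney test between the
    per-synapse SI summaries of the two polarities."""
    a = np.asarray(si_posterior, dtype=float)
    b = np.asarray(si_anterior, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both polarity groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    sem_a = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else np.nan
    sem_b = b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else np.nan
    return PolarityComparison(
        mean_posterior=float(a.mean()),
        sem_posterior=float(sem_a),
        mean_anterior=float(b.mean()),
        sem_anterior=float(sem_b),
        p_value=float(res.pvalue),
        statistic=statistic,
        low_n=bool(min(a.size, b.size) < 3),
    )
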