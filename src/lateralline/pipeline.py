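"""End-to-end orchestration: synthetic data -> spikes -> ΔF/F -> suppression
statistics -> machine-readable report.

A single seed governs every stochastic stage through named sub-streams, so
re-running a config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as llio
from .coupling import (
    bout_fluorescence_integral,
    cross_correlate_lag,
    spike_count_integral_correlation,
)
from .ephys import (
    EphysTrace,
    SpikeTrain,
    detect_spikes,
    downsample_to_frames,
    filter_motor_trace,
    segment_bouts,
)
from .imaging import (
    FluoTrace,
    Movie,
    compute_dff,
    extract_traces,
    segment_rois,
    subtract_background,
)
from .suppression import (
    StimulusEpoch,
    build_trial_set,
    classify_synapse,
    compare_polarity_groups,
    compute_si_profiles,
    fit_hill,
    polarity_binomial_test,
    pool_si_vs_spikes,
    synapse_mean_si,
)
from .synthgen import (
    GroundTruth,
    SimConfig,
    simulate_efferent_calcium,
    simulate_motor_recording,
    simulate_movie,
    simulate_stimulus_protocol,
    simulate_synapse_traces,
)

__all__ = ["PipelineConfig", "Report", "run_pipeline", "make_fixture", "infer_polarity"]

log = logging.getLogger("lateralline.pipeline")

__version__ = "0.1.0"


class PipelineConfig(BaseModel):
    """Everything the pipeline needs: a simulation block (or input paths)
    plus the per-stage analysis parameters."""

    sim: SimConfig = Field(default_factory=SimConfig)
    movie_path: str | None = None
    ephys_path: str | None = None
    epochs_path: str | None = None

    use_movie: bool = True  # render + segment a movie (off: analyse traces directly)

    # ephys stage
    threshold_mads: float = 5.0
    spike_polarity: str = "abs"
    refractory: float = 0.002
    max_isi: float = 0.2

    # imaging stage
    background_percentile: float = 5.0
    seed_quantile: float = 0.98
    grow_threshold: float = 0.5
    min_roi_size: int = 4
    baseline_window: float = 10.0
    registration: str = "none"  # hook for real data; synthetic movies are drift-free

    # suppression stage
    ns_window: float = 0.05
    alpha: float = 0.05
    si_statistic: str = "mean_si"

    # coupling stage
    max_lag: float = 0.5
    bout_integral_extension: float = 0.5

    seed: int = 0
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"outdir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class SynapseResult(BaseModel):
    synapse_id: int
    polarity: str
    label: str
    p_value: float | None
    u_statistic: float | None
    n_coincident: int
    n_noncoincident: int
    mean_si: float | None
    max_si: float | None
    roi_size: int | None = None
    true_synapse: int | None = None  # ground-truth index (synthetic data only)


class Report(BaseModel):
    """Machine-readable pipeline output (validates as its own JSON schema)."""

    n_synapses: int
    synapses: list[SynapseResult]
    contingency: dict[str, int]
    suppressed_fraction: float | None
    binomial_null_p: float | None
    hill_si_max: float | None
    hill_n_half: float | None
    hill_si_max_se: float | None
    hill_n_half_se: float | None
    hill_n_points: int | None
    group_mean_si_posterior: float | None
    group_sem_si_posterior: float | None
    group_mean_si_anterior: float | None
    group_sem_si_anterior: float | None
    group_p_value: float | None
    efferent_bout_integral_r: float | None
    glutamate_bout_integral_r: float | None
    xcorr_lag_s: float | None
    xcorr_extremum: float | None
    n_spikes_detected: int
    n_bouts: int
    config_hash: str
    seed: int
    version: str


def infer_polarity(dff: FluoTrace, epochs: list[StimulusEpoch]) -> str:
    """Assign hair-cell polarity from the data: the sign of pressure step
    that evokes the larger mean ΔF/F response."""
    t = dff.frame_times
    means = {}
    for sign in (1, -1):
        sel = np.zeros(t.size, dtype=bool)
        for ep in epochs:
            if ep.sign == sign:
                sel |= (t > ep.onset) & (t <= ep.offset)
        means[sign] = float(dff.values[sel].mean()) if np.any(sel) else -np.inf
    return "posterior" if means[1] >= means[-1] else "anterior"


def _nan_to_none(x: float | None) -> float | None:
    if x is None:
        return None
    x = float(x)
    return x if np.isfinite(x) else None


def _match_rois_to_truth(masks, gt: GroundTruth) -> list[int | None]:
    """Best-overlap assignment of segmented ROIs to ground-truth blobs."""
    if gt.roi_masks is None:
        return [None] * len(masks)
    true_sets = [set(map(tuple, m.pixels)) for m in gt.roi_masks]
    out = []
    for m in masks:
        pix = set(map(tuple, m.pixels))
        best, best_j = 0.0, None
        for j, ts in enumerate(true_sets):
            inter = len(pix & ts)
            if inter:
                jac = inter / len(pix | ts)
                if jac > best:
                    best, best_j = jac, j
        out.append(best_j if best >= 0.2 else None)
    return out


def run_pipeline(cfg: PipelineConfig) -> Report:
    """Execute synthgen -> ephys -> imaging -> suppression -> coupling and
    assemble the report.  Deterministic for a given config."""
    t_start = time.time()
    sim = cfg.sim.model_copy(update={"seed": cfg.seed})

    file_based = bool(cfg.movie_path or cfg.ephys_path or cfg.epochs_path)
    if file_based:
        if not (cfg.movie_path and cfg.ephys_path and cfg.epochs_path):
            raise ValueError(
                "file-based runs need movie_path, ephys_path and epochs_path"
            )
        raw_trace = llio.read_ephys_h5(cfg.ephys_path)
        epochs = llio.read_epochs(cfg.epochs_path)
        movie = llio.read_movie(cfg.movie_path, frame_rate=sim.frame_rate)
        gt = GroundTruth()
        syn_traces = None
        efferent = None
        log.info(
            "inputs: %d ephys samples, %d epochs, %d-frame movie",
            raw_trace.samples.size, len(epochs), movie.n_frames,
        )
    else:
        # ------------------------------------------------------------ synthgen
        raw_trace, gt = simulate_motor_recording(sim)
        epochs = simulate_stimulus_protocol(sim)
        true_spikes = SpikeTrain(times=gt.spike_times, source_rate=sim.ephys_rate)
        syn_traces, gt2 = simulate_synapse_traces(sim, true_spikes, epochs)
        gt.merge(gt2)
        efferent = simulate_efferent_calcium(sim, true_spikes)
        log.info(
            "synthgen: %d samples, %d true spikes, %d epochs, %d synapses",
            raw_trace.samples.size, gt.spike_times.size, len(epochs), len(syn_traces),
        )

    # ------------------------------------------------------------------- ephys
    filtered = filter_motor_trace(raw_trace)
    spikes = detect_spikes(
        filtered,
        threshold_mads=cfg.threshold_mads,
        polarity=cfg.spike_polarity,
        refractory=cfg.refractory,
    )
    bouts = segment_bouts(spikes, max_isi=cfg.max_isi)
    log.info("ephys: %d spikes detected, %d bouts", len(spikes), len(bouts))

    # ----------------------------------------------------------------- imaging
    first_onset = min(e.onset for e in epochs) if epochs else None
    if cfg.use_movie or file_based:
        if not file_based:
            movie, gt3 = simulate_movie(sim, syn_traces)
            gt.merge(gt3)
        movie_bs = subtract_background(movie, percentile=cfg.background_percentile)
        masks = segment_rois(
            movie_bs,
            seed_quantile=cfg.seed_quantile,
            grow_threshold=cfg.grow_threshold,
            min_size=cfg.min_roi_size,
        )
        raw_traces = extract_traces(movie_bs, masks)
        matches = _match_rois_to_truth(masks, gt)
        roi_sizes = [len(m) for m in masks]
        log.info("imaging: %d ROIs from %d-frame movie", len(masks), movie.n_frames)
    else:
        raw_traces = syn_traces
        matches = list(range(len(syn_traces)))
        roi_sizes = [None] * len(syn_traces)

    dffs = [
        compute_dff(tr, first_stim_onset=first_onset, baseline_window=cfg.baseline_window)
        for tr in raw_traces
    ]

    # -------------------------------------------------------------- suppression
    results: list[SynapseResult] = []
    suppressed_profiles = []
    group_si = {"posterior": [], "anterior": []}
    for i, dff in enumerate(dffs):
        pol = infer_polarity(dff, epochs) if epochs else "posterior"
        entry = dict(
            synapse_id=i,
            polarity=pol,
            roi_size=roi_sizes[i],
            true_synapse=matches[i],
        )
        try:
            ts = build_trial_set(
                dff, epochs, spikes, pol, synapse_id=i, ns_window=cfg.ns_window
            )
        except ValueError:
            results.append(
                SynapseResult(
                    **entry, label="untestable", p_value=None, u_statistic=None,
                    n_coincident=0, n_noncoincident=0, mean_si=None, max_si=None,
                )
            )
            continue
        cls = classify_synapse(ts, alpha=cfg.alpha)
        mean_si = max_si = None
        if cls.label != "untestable" and ts.quiet_trials:
            try:
                profiles = compute_si_profiles(ts)
            except ValueError:
                profiles = None  # degenerate R_o (e.g. no evoked response)
            if profiles is not None:
                mean_si = _nan_to_none(synapse_mean_si(profiles, "mean_si"))
                max_si = _nan_to_none(synapse_mean_si(profiles, "max_si"))
                if cls.label == "suppressed":
                    suppressed_profiles.extend(profiles)
                    if mean_si is not None:
                        group_si[pol].append(mean_si)
        results.append(
            SynapseResult(
                **entry,
                label=cls.label,
                p_value=_nan_to_none(cls.p_value),
                u_statistic=_nan_to_none(cls.u_statistic),
                n_coincident=cls.n_coincident,
                n_noncoincident=cls.n_noncoincident,
                mean_si=mean_si,
                max_si=max_si,
            )
        )

    contingency = {}
    for pol in ("posterior", "anterior"):
        for label in ("suppressed", "unaffected", "untestable"):
            contingency[f"{pol}_{label}"] = sum(
                1 for r in results if r.polarity == pol and r.label == label
            )
    n_sup = sum(1 for r in results if r.label == "suppressed")
    n_cls = sum(1 for r in results if r.label != "untestable")
    suppressed_fraction = n_sup / n_cls if n_cls else None
    n_post = sum(
        1 for r in results if r.polarity == "posterior" and r.label != "untestable"
    )
    binom_p = (
        polarity_binomial_test(suppressed_fraction, n_post)
        if suppressed_fraction is not None
        else None
    )

    hill = None
    if suppressed_profiles:
        try:
            pooled = pool_si_vs_spikes(suppressed_profiles)
            pts = pooled.attrs["points"]
            hill = fit_hill(pts["n_s"].to_numpy(), pts["si"].to_numpy())
        except (ValueError, RuntimeError) as exc:
            log.warning("suppression: Hill fit unavailable (%s)", exc)
            pooled = None
    else:
        pooled = None

    comparison = None
    if group_si["posterior"] and group_si["anterior"]:
        comparison = compare_polarity_groups(
            group_si["posterior"], group_si["anterior"], statistic=cfg.si_statistic
        )
    log.info(
        "suppression: %d/%d suppressed, hill=%s",
        n_sup, len(results), f"{hill.si_max:.3f}/{hill.n_half:.3f}" if hill else None,
    )

    # ----------------------------------------------------------------- coupling
    efferent_r = glut_r = lag_s = lag_val = None
    frame_times = dffs[0].frame_times if dffs else np.empty(0)
    frame_counts = downsample_to_frames(spikes, frame_times)
    usable_bouts = [
        b
        for b in bouts
        if frame_times.size
        and b.start - 0.5 >= frame_times[0]
        and b.end + cfg.bout_integral_extension <= frame_times[-1]
    ]
    if len(usable_bouts) >= 3:
        if efferent is not None:
            try:
                eff_metrics = [
                    bout_fluorescence_integral(efferent, b, cfg.bout_integral_extension)
                    for b in usable_bouts
                ]
                efferent_r = spike_count_integral_correlation(eff_metrics)
            except ValueError:
                pass
        sup_idx = [i for i, r in enumerate(results) if r.label == "suppressed"]
        if sup_idx:
            best = min(sup_idx, key=lambda i: results[i].p_value or 1.0)
            try:
                glut_metrics = [
                    bout_fluorescence_integral(dffs[best], b, cfg.bout_integral_extension)
                    for b in usable_bouts
                ]
                glut_r = spike_count_integral_correlation(glut_metrics)
                xc = cross_correlate_lag(dffs[best], frame_counts, cfg.max_lag)
                lag_s, lag_val = xc.extremum_lag, xc.extremum_value
            except ValueError:
                pass

    report = Report(
        n_synapses=len(results),
        synapses=results,
        contingency=contingency,
        suppressed_fraction=_nan_to_none(suppressed_fraction),
        binomial_null_p=_nan_to_none(binom_p),
        hill_si_max=_nan_to_none(hill.si_max) if hill else None,
        hill_n_half=_nan_to_none(hill.n_half) if hill else None,
        hill_si_max_se=_nan_to_none(hill.si_max_se) if hill else None,
        hill_n_half_se=_nan_to_none(hill.n_half_se) if hill else None,
        hill_n_points=hill.n_points if hill else None,
        group_mean_si_posterior=_nan_to_none(comparison.mean_posterior) if comparison else None,
        group_sem_si_posterior=_nan_to_none(comparison.sem_posterior) if comparison else None,
        group_mean_si_anterior=_nan_to_none(comparison.mean_anterior) if comparison else None,
        group_sem_si_anterior=_nan_to_none(comparison.sem_anterior) if comparison else None,
        group_p_value=_nan_to_none(comparison.p_value) if comparison else None,
        efferent_bout_integral_r=_nan_to_none(efferent_r),
        glutamate_bout_integral_r=_nan_to_none(glut_r),
        xcorr_lag_s=_nan_to_none(lag_s),
        xcorr_extremum=_nan_to_none(lag_val),
        n_spikes_detected=len(spikes),
        n_bouts=len(bouts),
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        version=__version__,
    )

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.model_dump_json(indent=2))
        llio.write_spikes(out / "spikes.csv", spikes)
        pd.DataFrame(
            [{"start_s": b.start, "end_s": b.end, "n_spikes": b.n_spikes} for b in bouts]
        ).to_csv(out / "bouts.csv", index=False)
        pd.DataFrame([r.model_dump() for r in results]).to_csv(
            out / "classifications.csv", index=False
        )
        if pooled is not None:
            pooled.to_csv(out / "pooled_si.csv")
        llio.write_ground_truth(out / "ground_truth.json", gt)
    log.info("pipeline: done in %.1f s", time.time() - t_start)
    return report


def make_fixture(name: str, outdir: str | Path, seed: int = 0) -> SimConfig:
    """Write a self-contained synthetic dataset (movie, ephys, protocol,
    ground truth, config) to ``outdir``.

    ``tiny`` is a 2-synapse, 60 s dataset that runs through the full
    pipeline in seconds; ``paper_default`` mirrors the headline study
    conditions; ``null`` has zero true suppression.
    """
    presets = {
        "tiny": SimConfig.tiny,
        "paper_default": SimConfig.paper_default,
        "null": SimConfig.null,
    }
    if name not in presets:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(presets)}")
    cfg = presets[name](seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trace, gt = simulate_motor_recording(cfg)
    epochs = simulate_stimulus_protocol(cfg)
    spikes = SpikeTrain(times=gt.spike_times, source_rate=cfg.ephys_rate)
    traces, gt2 = simulate_synapse_traces(cfg, spikes, epochs)
    gt.merge(gt2)
    movie, gt3 = simulate_movie(cfg, traces)
    gt.merge(gt3)
    llio.write_movie(out / "movie.tif", movie)
    llio.write_ephys_h5(out / "ephys.h5", trace)
    llio.write_epochs(out / "protocol.csv", epochs)
    llio.write_ground_truth(out / "ground_truth.json", gt)
    (out / "config.json").write_text(cfg.model_dump_json(indent=2))
    return cfg
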