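"""Ground-truthed synthetic datasets for the lateral-line suppression pipeline.

No public recordings exist for this preparation, so the generator emulates
the statistical structure the analysis assumes and every downstream stage is
tested against known ground truth:

* bout-structured motor-nerve spiking (renewal process of bouts, near-Poisson
  spiking with a short refractory period within bouts) rendered as a 5 kHz
  voltage trace with a biphasic spike template, Gaussian noise and a 50 Hz
  mains component;
* alternating positive/negative pressure-step protocols (posterior/anterior
  cupula deflections);
* glutamate-release traces for two opposing hair-cell polarities, whose gain
  is reduced by motor spikes following a Hill relation of the spike count in
  the preceding 50 ms, with ~90 % recovery within 100 ms of the last spike;
  release is low-pass filtered by single-exponential indicator kinetics and
  sampled at the imaging frame rate with additive (optionally AR(1)) noise;
* movies rendering each synapse as a Gaussian blob on a static background
  with shot-like noise.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from pydantic import BaseModel, Field, model_validator

from .ephys import EphysTrace, SpikeTrain
from .imaging import FluoTrace, Movie, RoiMask
from .suppression import StimulusEpoch

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_motor_recording",
    "simulate_stimulus_protocol",
    "simulate_synapse_traces",
    "simulate_efferent_calcium",
    "simulate_movie",
    "instantaneous_si",
]


class SimConfig(BaseModel):
    """Parameters of the synthetic experiment.

    The defaults constitute the ``paper_default`` preset: a 5 kHz nerve
    recording and 20 Hz imaging of 41 hair-cell synapses (16 posterior, all
    suppressed; 25 anterior, 13 suppressed) stimulated with alternating
    pressure steps, with suppression following a Hill relation of the spike
    count in the preceding 50 ms.  ``si_amp_posterior`` / ``si_amp_anterior``
    are the group ground-truth SI amplitudes on the measured scale,
    calibrated so that the full pipeline reproduces group-mean SIs of about
    1.20 (posterior) and 0.54 (anterior) and a pooled Hill amplitude of
    about 1.05.
    """

    # clocks
    ephys_rate: float = Field(5000.0, gt=0, description="nerve sampling rate (samples/s)")
    frame_rate: float = Field(20.0, ge=20.0, le=50.0, description="imaging rate (frames/s)")
    duration: float = Field(180.0, gt=0, description="recording length (s)")
    sim_grid_rate: float = Field(1000.0, gt=0, description="internal release-dynamics grid (samples/s)")

    # motor activity
    bout_rate: float = Field(0.25, ge=0, description="swim-bout onset rate (bouts/s)")
    bout_duration_mean: float = Field(1.0, gt=0, description="mean bout length (s)")
    within_bout_spike_rate: float = Field(300.0, ge=0, description="mean spike rate inside a bout (spikes/s)")
    within_bout_rate_shape: float = Field(2.0, gt=0, description="gamma shape of the per-bout rate (bout-strength variability); inf = fixed rate")
    refractory: float = Field(0.0025, ge=0, description="minimum inter-spike interval (s)")
    spike_amplitude: float = Field(1.0, gt=0, description="spike template peak (V)")
    spike_snr: float = Field(10.0, gt=0, description="spike peak / raw noise SD")
    mains_amplitude: float = Field(0.2, ge=0, description="50 Hz component amplitude (V)")

    # stimulus protocol
    first_stim_onset: float = Field(12.0, gt=0, description="onset of the first pressure step (s)")
    stim_duration: float = Field(1.0, gt=0, description="pressure-step length (s)")
    stim_interval: float = Field(1.0, gt=0, description="gap between steps (s)")
    n_steps: int | None = Field(None, ge=0, description="number of steps (None = fill the recording)")

    # synapse populations
    n_synapses_posterior: int = Field(16, ge=0)
    n_synapses_anterior: int = Field(25, ge=0)
    n_anterior_suppressed: int = Field(13, ge=0)

    # suppression ground truth
    si_max_true: float = Field(1.05, ge=0, description="pooled Hill amplitude the preset is calibrated to")
    n_half_true: float = Field(1.12, gt=0, description="spike count at half-maximal suppression")
    si_mean_posterior: float = Field(1.20, ge=0, description="target posterior group-mean SI")
    si_mean_anterior: float = Field(0.54, ge=0, description="target anterior group-mean SI")
    si_amp_posterior: float = Field(1.63, ge=0, description="calibrated posterior SI amplitude (measured scale)")
    si_amp_anterior: float = Field(0.69, ge=0, description="calibrated anterior SI amplitude (measured scale)")
    recovery_tau: float = Field(0.03, gt=0, description="suppression recovery time constant (s); >=90% recovery within 100 ms")

    # indicator and noise
    indicator_tau_decay: float = Field(0.04, gt=0, description="indicator decay time constant (s)")
    evoked_dff: float = Field(1.0, ge=0, description="unsuppressed evoked response plateau (ΔF/F)")
    noise_sd: float = Field(0.1, ge=0, description="additive trace noise (ΔF/F units)")
    noise_ar: float = Field(0.0, ge=0, lt=1, description="AR(1) coefficient of the trace noise")
    baseline_F: float = Field(100.0, gt=0, description="baseline fluorescence (camera counts)")

    # movie rendering
    frame_height: int = Field(96, gt=0)
    frame_width: int = Field(96, gt=0)
    blob_sigma: float = Field(1.5, gt=0, description="synapse blob size (pixels)")
    blob_amplitude: float = Field(1.0, gt=0, description="blob peak weight on the synapse trace")
    background_counts: float = Field(20.0, ge=0, description="static background level (counts)")
    shot_noise: bool = Field(True, description="apply Poisson noise to movie pixels")

    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.frame_rate > self.ephys_rate:
            raise ValueError("frame_rate must not exceed ephys_rate")
        if self.sim_grid_rate < 4 * self.frame_rate:
            raise ValueError("sim_grid_rate too low for the frame rate")
        if self.refractory > 0 and self.within_bout_spike_rate >= 1.0 / self.refractory:
            raise ValueError("within_bout_spike_rate incompatible with refractory period")
        if self.n_anterior_suppressed > self.n_synapses_anterior:
            raise ValueError("n_anterior_suppressed exceeds n_synapses_anterior")
        return self

    # ------------------------------------------------------------------ presets
    @classmethod
    def paper_default(cls, **overrides) -> "SimConfig":
        """The headline study conditions (the class defaults)."""
        return cls(**overrides)

    @classmethod
    def tiny(cls, **overrides) -> "SimConfig":
        """A two-synapse, 60 s dataset that runs through the full pipeline
        in seconds."""
        kw = dict(
            duration=60.0,
            n_synapses_posterior=1,
            n_synapses_anterior=1,
            n_anterior_suppressed=1,
            frame_height=32,
            frame_width=32,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """No true suppression; weakly autocorrelated trace noise."""
        kw = dict(
            si_amp_posterior=0.0,
            si_amp_anterior=0.0,
            n_anterior_suppressed=0,
            evoked_dff=0.0,
            noise_ar=0.3,
        )
        kw.update(overrides)
        return cls(**kw)

    # ---------------------------------------------------------------- helpers
    @property
    def n_synapses(self) -> int:
        return self.n_synapses_posterior + self.n_synapses_anterior

    def synapse_polarity(self, i: int) -> str:
        if not 0 <= i < self.n_synapses:
            raise IndexError(i)
        return "posterior" if i < self.n_synapses_posterior else "anterior"

    def synapse_si_amplitude(self, i: int) -> float:
        """Ground-truth SI amplitude (measured scale) of synapse *i*."""
        if self.synapse_polarity(i) == "posterior":
            return self.si_amp_posterior
        return (
            self.si_amp_anterior
            if i - self.n_synapses_posterior < self.n_anterior_suppressed
            else 0.0
        )

    def synapse_suppressed(self, i: int) -> bool:
        return self.synapse_si_amplitude(i) > 0

    def rng(self, stream: str) -> np.random.Generator:
        """Named, reproducible random stream derived from the config seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )


_STREAMS = {"motor": 1, "traces": 2, "movie": 3, "efferent": 4}


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-based testing."""

    spike_times: np.ndarray | None = None
    bouts: list[tuple[float, float, int]] | None = None  # (start, end, n_spikes); n may be 0
    polarity: list[str] | None = None
    suppressed: list[bool] | None = None
    si_amplitude: np.ndarray | None = None
    si_state_frames: np.ndarray | None = None   # normalised suppression state per frame
    noiseless_dff: np.ndarray | None = None     # (n_synapses, n_frames)
    unsuppressed_dff: np.ndarray | None = None  # (n_synapses, n_frames)
    frame_times: np.ndarray | None = None
    roi_masks: list[RoiMask] | None = None
    blob_centers: np.ndarray | None = None

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        for name in self.__dataclass_fields__:
            v = getattr(other, name)
            if v is not None:
                setattr(self, name, v)
        return self


def instantaneous_si(cfg: SimConfig, n_spikes) -> float | np.ndarray:
    """Hill ground truth: SI a suppressed-population synapse would show for
    ``n_spikes`` motor spikes in the preceding 50 ms (pooled scale)."""
    n = np.asarray(n_spikes, dtype=float)
    out = cfg.si_max_true * n / (n + cfg.n_half_true)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------- motor

def _spike_template(rate: float, amplitude: float, f0: float = 800.0) -> np.ndarray:
    """Biphasic extracellular spike waveform: a Hann-windowed 1.5-cycle
    sine at ``f0`` (~1.8 ms).  Band-limited to the 300-1000 Hz passband so
    the zero-phase detection filter neither rings beyond the 2 ms merge
    window nor splits one spike into two threshold crossings."""
    n = max(int(round(1.5 * rate / f0)), 4)
    t = np.arange(n) / rate
    w = np.hanning(n)
    tmpl = w * np.sin(2.0 * np.pi * f0 * t)
    return amplitude * tmpl / np.abs(tmpl).max()


def simulate_bouts_and_spikes(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    """Bout windows and spike times.

    Bout onsets form a renewal process with exponential inter-onset
    intervals (rate ``bout_rate``); bout durations are exponential with mean
    ``bout_duration_mean``.  Each bout draws its own firing rate from a
    gamma distribution (mean ``within_bout_spike_rate``, shape
    ``within_bout_rate_shape``) — swim bouts vary in vigour — and spikes
    within the bout are Poisson at that rate, thinned to the refractory
    period.  Bout windows that happen to contain zero spikes are kept in
    the ground truth with ``n_spikes = 0``.
    """
    bouts: list[tuple[float, float, int]] = []
    spikes: list[np.ndarray] = []
    if cfg.bout_rate <= 0 or cfg.within_bout_spike_rate <= 0:
        return np.empty(0), bouts
    t = float(rng.exponential(1.0 / cfg.bout_rate))
    prev_end = -np.inf
    while t < cfg.duration:
        dur = float(rng.exponential(cfg.bout_duration_mean))
        end = min(t + dur, cfg.duration)
        if t > prev_end:  # skip bouts swallowed by the previous one
            rate_b = cfg.within_bout_spike_rate
            if np.isfinite(cfg.within_bout_rate_shape):
                rate_b = rng.gamma(
                    cfg.within_bout_rate_shape,
                    cfg.within_bout_spike_rate / cfg.within_bout_rate_shape,
                )
            n_exp = rng.poisson(rate_b * (end - t))
            st = np.sort(rng.uniform(t, end, size=n_exp))
            if cfg.refractory > 0 and st.size > 1:
                keep = [st[0]]
                for s in st[1:]:
                    if s - keep[-1] >= cfg.refractory:
                        keep.append(s)
                st = np.asarray(keep)
            bouts.append((t, end, int(st.size)))
            spikes.append(st)
            prev_end = end
        t += float(rng.exponential(1.0 / cfg.bout_rate))
    all_spikes = np.concatenate(spikes) if spikes else np.empty(0)
    # numerical guard: strictly increasing
    if all_spikes.size > 1:
        all_spikes = all_spikes[np.concatenate([[True], np.diff(all_spikes) > 0])]
    return all_spikes, bouts


def simulate_motor_recording(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[EphysTrace, GroundTruth]:
    """Raw 5 kHz nerve voltage: spike template at the true spike times plus
    Gaussian noise and a 50 Hz mains sinusoid."""
    rng = cfg.rng("motor") if rng is None else rng
    spike_times, bouts = simulate_bouts_and_spikes(cfg, rng)
    n = int(round(cfg.duration * cfg.ephys_rate))
    noise_sd = cfg.spike_amplitude / cfg.spike_snr
    v = rng.normal(0.0, noise_sd, size=n)
    if cfg.mains_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        v += cfg.mains_amplitude * np.sin(
            2 * np.pi * 50.0 * np.arange(n) / cfg.ephys_rate + phase
        )
    tmpl = _spike_template(cfg.ephys_rate, cfg.spike_amplitude)
    for s in spike_times:
        i0 = int(round(s * cfg.ephys_rate))
        i1 = min(i0 + tmpl.size, n)
        if i0 < n:
            v[i0:i1] += tmpl[: i1 - i0]
    gt = GroundTruth(spike_times=spike_times, bouts=bouts)
    return EphysTrace(samples=v, rate=cfg.ephys_rate, t0=0.0), gt


# ------------------------------------------------------------------ protocol

def simulate_stimulus_protocol(cfg: SimConfig) -> list[StimulusEpoch]:
    """Alternating positive/negative pressure steps, pairwise disjoint."""
    period = cfg.stim_duration + cfg.stim_interval
    epochs = []
    k = 0
    while True:
        if cfg.n_steps is not None and k >= cfg.n_steps:
            break
        onset = cfg.first_stim_onset + k * period
        offset = onset + cfg.stim_duration
        if cfg.n_steps is None and offset > cfg.duration:
            break
        epochs.append(StimulusEpoch(onset=onset, offset=offset, sign=1 if k % 2 == 0 else -1))
        k += 1
    return epochs


# -------------------------------------------------------------- release/gain

def _suppression_state(
    h: np.ndarray, dt: float, recovery_tau: float, chunk: int = 2048
) -> np.ndarray:
    """Running max-with-exponential-decay of the Hill drive ``h``:

    s[i] = max(h[i], s[i-1] * exp(-dt/tau))

    i.e. suppression engages within one sample of a spike and relaxes back
    with ``recovery_tau``.  Vectorised with a chunked cumulative-maximum
    trick to avoid overflow of the growing exponential weights.
    """
    d = np.exp(-dt / recovery_tau)
    # keep d**(-chunk) well below float overflow
    chunk = max(8, min(chunk, int(600.0 * recovery_tau / dt)))
    out = np.empty_like(h)
    carry = 0.0  # state at the sample preceding the current chunk
    n = h.size
    for i0 in range(0, n, chunk):
        seg = h[i0 : i0 + chunk]
        m = seg.size
        j = np.arange(m, dtype=float)
        # s[i] = d^i * max(carry*d, max_{j<=i} h[j]*d^-j); d^-j stays < 1e23
        # for the chunk sizes used, so the products remain finite.
        cum = np.maximum.accumulate(seg * d**(-j))
        s_seg = np.maximum(cum, carry * d) * d**j
        out[i0 : i0 + m] = s_seg
        carry = s_seg[-1]
    return out


def _frame_average(x: np.ndarray, grid_rate: float, frame_times: np.ndarray) -> np.ndarray:
    """Average a fine-grid series over each frame's exposure interval."""
    dt = np.median(np.diff(frame_times)) if frame_times.size > 1 else frame_times[0]
    edges = np.concatenate([[frame_times[0] - dt], frame_times])
    idx = np.clip(np.round(edges * grid_rate).astype(int), 0, x.size)
    sums = np.add.reduceat(x, idx[:-1])
    counts = np.maximum(np.diff(idx), 1)
    # reduceat quirk: when idx[i] == idx[i+1] it returns x[idx[i]]
    return sums / np.diff(idx).clip(min=1)


def frame_timestamps(cfg: SimConfig) -> np.ndarray:
    """End-of-exposure timestamps: frame k covers ((k)/fr, (k+1)/fr]."""
    n_frames = int(np.floor(cfg.duration * cfg.frame_rate))
    return np.arange(1, n_frames + 1) / cfg.frame_rate


def simulate_synapse_traces(
    cfg: SimConfig,
    spikes: SpikeTrain,
    protocol: list[StimulusEpoch],
    rng: np.random.Generator | None = None,
) -> tuple[list[FluoTrace], GroundTruth]:
    """Per-synapse fluorescence traces with ground-truthed suppression.

    Release rate = spontaneous baseline + polarity-matched evoked plateau
    during matching-sign epochs, multiplied by a gain ``g(t) = 1 - S(t)``
    where ``S`` is the release-level suppression derived from the Hill
    function of the spike count in the preceding 50 ms (exponential recovery
    with ``recovery_tau``).  Release is filtered by the indicator decay
    kernel, averaged over each frame's exposure and read out in camera
    counts with additive Gaussian (optionally AR(1)) noise.
    """
    rng = cfg.rng("traces") if rng is None else rng
    st = spikes.times
    if st.size and (st[0] < -1e-9 or st[-1] > cfg.duration + 1e-9):
        raise ValueError("spike train extends outside the configured duration")
    for ep in protocol:
        if ep.offset > cfg.duration + 1e-9:
            raise ValueError("stimulus protocol extends beyond the recording")

    gr = cfg.sim_grid_rate
    n = int(round(cfg.duration * gr))
    tgrid = (np.arange(n) + 1) / gr

    # Hill drive of the preceding-50 ms spike count, then recovery dynamics
    hi = np.searchsorted(st, tgrid, side="right")
    lo = np.searchsorted(st, tgrid - 0.05, side="right")
    n_window = (hi - lo).astype(float)
    h = n_window / (n_window + cfg.n_half_true)
    s_state = _suppression_state(h, 1.0 / gr, cfg.recovery_tau)

    # evoked drive per polarity (indicator-free, rectangular)
    evoked = {"posterior": np.zeros(n), "anterior": np.zeros(n)}
    for ep in protocol:
        i0, i1 = np.searchsorted(tgrid, [ep.onset, ep.offset], side="right")
        key = "posterior" if ep.sign == 1 else "anterior"
        evoked[key][i0:i1] = cfg.evoked_dff

    # indicator kernel as a single-pole IIR filter with unit DC gain
    alpha = 1.0 - np.exp(-1.0 / (gr * cfg.indicator_tau_decay))
    from scipy.signal import lfilter

    frame_times = frame_timestamps(cfg)
    # measured-scale SI amplitude -> release-level suppression scale
    rel_scale = cfg.evoked_dff / (1.0 + cfg.evoked_dff)

    traces: list[FluoTrace] = []
    polarity: list[str] = []
    suppressed: list[bool] = []
    amps = np.empty(cfg.n_synapses)
    noiseless = np.empty((cfg.n_synapses, frame_times.size))
    unsup = np.empty((cfg.n_synapses, frame_times.size))

    fluor_cache: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] = {}
    for i in range(cfg.n_synapses):
        pol = cfg.synapse_polarity(i)
        amp = cfg.synapse_si_amplitude(i)
        amps[i] = amp
        polarity.append(pol)
        suppressed.append(amp > 0)
        key = (pol, amp)
        if key not in fluor_cache:
            drive = 1.0 + evoked[pol]
            gain = np.clip(1.0 - amp * rel_scale * s_state, 0.0, None)
            release = gain * drive
            f = lfilter([alpha], [1.0, -(1.0 - alpha)], release, zi=[1.0 - alpha])[0]
            f0 = lfilter([alpha], [1.0, -(1.0 - alpha)], drive, zi=[1.0 - alpha])[0]
            fluor_cache[key] = (
                _frame_average(f, gr, frame_times) - 1.0,
                _frame_average(f0, gr, frame_times) - 1.0,
            )
        dff, dff0 = fluor_cache[key]
        noiseless[i] = dff
        unsup[i] = dff0
        noise = rng.normal(0.0, 1.0, size=frame_times.size)
        if cfg.noise_ar > 0:
            from scipy.signal import lfilter as _lf

            noise = _lf([np.sqrt(1 - cfg.noise_ar**2)], [1.0, -cfg.noise_ar], noise)
        counts = cfg.baseline_F * (1.0 + dff + cfg.noise_sd * noise)
        traces.append(
            FluoTrace(
                values=counts,
                frame_times=frame_times.copy(),
                roi_label=i + 1,
                units="counts",
            )
        )

    gt = GroundTruth(
        polarity=polarity,
        suppressed=suppressed,
        si_amplitude=amps,
        si_state_frames=_frame_average(s_state, gr, frame_times),
        noiseless_dff=noiseless,
        unsuppressed_dff=unsup,
        frame_times=frame_times,
    )
    return traces, gt


def simulate_efferent_calcium(
    cfg: SimConfig,
    spikes: SpikeTrain,
    rng: np.random.Generator | None = None,
    tau_gcamp: float = 0.4,
    amp_per_spike: float = 0.05,
) -> FluoTrace:
    """A GCaMP-like efferent-terminal calcium proxy: spike deltas convolved
    with a slow exponential, sampled at the frame rate, mild noise."""
    rng = cfg.rng("efferent") if rng is None else rng
    gr = cfg.sim_grid_rate
    n = int(round(cfg.duration * gr))
    drive = np.zeros(n)
    idx = np.clip((spikes.times * gr).astype(int), 0, n - 1)
    np.add.at(drive, idx, 1.0)
    kernel_decay = np.exp(-1.0 / (gr * tau_gcamp))
    from scipy.signal import lfilter

    cal = lfilter([1.0], [1.0, -kernel_decay], drive) * amp_per_spike
    frame_times = frame_timestamps(cfg)
    dff = _frame_average(cal, gr, frame_times)
    dff = dff + rng.normal(0.0, cfg.noise_sd * 0.1, size=dff.size)
    return FluoTrace(values=dff, frame_times=frame_times, baseline_F=1.0, units="dff")


# --------------------------------------------------------------------- movie

def blob_layout(cfg: SimConfig) -> np.ndarray:
    """Deterministic grid of blob centers with a 4-sigma margin."""
    margin = int(np.ceil(4 * cfg.blob_sigma))
    spacing = int(np.ceil(8 * cfg.blob_sigma))
    rows = np.arange(margin, cfg.frame_height - margin + 1, spacing)
    cols = np.arange(margin, cfg.frame_width - margin + 1, spacing)
    centers = [(r, c) for r in rows for c in cols]
    if len(centers) < cfg.n_synapses:
        raise ValueError(
            f"cannot place {cfg.n_synapses} disjoint blobs in a "
            f"{cfg.frame_height}x{cfg.frame_width} frame"
        )
    return np.asarray(centers[: cfg.n_synapses], dtype=int)


def simulate_movie(
    cfg: SimConfig,
    traces: list[FluoTrace],
    rng: np.random.Generator | None = None,
) -> tuple[Movie, GroundTruth]:
    """Render synapse traces as Gaussian blobs on a static background.

    Every blob pixel shares its synapse's trace scaled by the blob profile;
    shot-like Poisson noise is applied per pixel when ``shot_noise`` is on.
    Ground truth includes the pixel masks (pixels within 2 sigma of each
    center), which are pairwise disjoint by construction.
    """
    rng = cfg.rng("movie") if rng is None else rng
    if not traces:
        raise ValueError("no traces to render")
    ft = traces[0].frame_times
    for tr in traces[1:]:
        if tr.frame_times.size != ft.size or not np.allclose(tr.frame_times, ft):
            raise ValueError("traces must share a common frame clock")
    centers = blob_layout(cfg)
    h, w = cfg.frame_height, cfg.frame_width
    movie = np.empty((ft.size, h, w), dtype=np.float32)
    movie.fill(np.float32(cfg.background_counts))
    masks = []
    half = int(np.ceil(3 * cfg.blob_sigma))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    profile = (
        cfg.blob_amplitude * np.exp(-(yy**2 + xx**2) / (2 * cfg.blob_sigma**2))
    ).astype(np.float32)
    for i, (r, c) in enumerate(centers[: len(traces)]):
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        movie[:, r0:r1, c0:c1] += (
            traces[i].values.astype(np.float32)[:, None, None] * profile[None]
        )
        in_mask = (yy**2 + xx**2) <= (2 * cfg.blob_sigma) ** 2
        coords = np.argwhere(in_mask) + [r0, c0]
        masks.append(RoiMask(pixels=coords, label=i + 1))
    np.maximum(movie, 0.0, out=movie)
    if cfg.shot_noise:
        movie = rng.poisson(movie).astype(np.uint16)
    else:
        movie = np.round(movie).astype(np.uint16)
    gt = GroundTruth(roi_masks=masks, blob_centers=centers[: len(traces)])
    return Movie(pixels=movie, frame_times=ft.copy()), gt
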