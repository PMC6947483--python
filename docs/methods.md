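# Methods

This note documents the models, parameter choices and numerical decisions
behind `lateralline`, and what the synthetic benchmarks do and do not show
about real data.

## The measurement model

A neuromast contains hair cells of two opposing polarities: posterior
deflection of the cupula depolarises one population, anterior deflection
the other. Each hair cell releases glutamate tonically from ribbon
synapses; a fluorescent glutamate indicator on the postsynaptic afferent
reports that release at the imaging frame rate. During fictive swimming
the motor nerve fires in discrete bouts, and cholinergic efferent input
reduces the gain of hair-cell transmission within tens of milliseconds.

The analysis quantifies this gain change with the suppression index. For
each stimulus presentation (a pressure step deflecting the cupula),
`R_m(t)` is the ΔF/F trace of one trial and `R_o(t)` the frame-wise mean
over *quiet* trials (no motor spike from 50 ms before onset to offset):

    SI(t) = (R_o(t) − R_m(t)) / R_o(t)

SI is 0 for no suppression, 1 when the evoked response is nulled, and
above 1 when spontaneous release is blocked as well, driving the signal
below its pre-stimulus baseline. Negative values simply mean the trial
exceeded the quiet mean and are kept. SI is related to the motor spike
count `N_s` in the 50 ms window preceding each frame (one frame interval
at 20 Hz) and pooled across all frames, trials and suppressed synapses;
the pooled cloud is summarised by the Hill relation
`SI(N_s) = SI_max · N_s / (N_s + N_1/2)`.

## Stage parameters

| parameter | default | why |
|---|---|---|
| band-pass | 300–1000 Hz, order-2 Butterworth, zero phase | standard motor-nerve band; forward-backward filtering so the 50 ms lag analysis sees no filter latency |
| notch | 50 Hz, Q = 30 | mains rejection |
| spike threshold | 5 × MAD × 1.4826 on the rectified filtered trace | robust to the spikes themselves; polarity configurable for negative-going units |
| refractory merge | 2 ms | one detection per biphasic waveform |
| bout boundary | max inter-spike interval 200 ms | between the ~100 ms recovery scale and the seconds-scale inter-bout quiescence |
| rate kernel | Gaussian, FWHM 100 ms, unit area | smoothed firing rate whose integral equals the spike count |
| background | per-frame 5th-percentile scalar, clipped at 0 | automated replacement for a manual background ROI; valid when most pixels are background |
| ROI seeds | neighbour-correlation above the 0.98 quantile | pixels sharing a time course with their 8-neighbours mark synapses |
| ROI growth | Pearson r ≥ 0.5 against the ROI mean trace, 8-connected, min 4 px | contiguity is enforced, so identical but distant signals stay separate ROIs |
| ΔF/F baseline | mean of first 10 s, truncated at first stimulus onset | pre-stimulus fluorescence defines F |
| SI guard | R_o ≥ 3 × SE(R_o) | frames with near-zero quiet response give unstable ratios and are marked invalid rather than clipped |
| N_s window | 50 ms | one frame interval at 20 Hz; kept separate from the coincidence window so other frame rates remain correct |
| classification | one-tailed Mann-Whitney U, α = 0.05, coincident-lower alternative | suppressed iff p < α; *untestable* when motor activity never overlapped a stimulus; no multiple-testing correction across synapses is applied |
| Hill fit | least squares on the pooled raw points, si_max ≥ 0, n_half > 0 | pooling the points weights each spike-count level by how often it occurred; grouped/SEM-weighted fitting is available via the pooled table |

## The synthetic generator

The generator emulates the statistical structure the analysis assumes and
provides ground truth for every stage.

*Motor activity.* Bout onsets are a renewal process (exponential
inter-onset intervals, 0.25 bouts/s); durations are exponential
(mean 1.0 s). Each bout draws its own firing rate from a gamma
distribution (mean 300 spikes/s, shape 2) — swim bouts vary in vigour,
which is also what makes per-bout spike counts informative for the
coupling analyses — and spikes are Poisson at that rate with a 2.5 ms
refractory period. The voltage trace is a Hann-windowed 1.5-cycle 800 Hz
biphasic template at the spike times plus Gaussian noise (peak SNR 10) and
a 50 Hz mains sinusoid at 0.2 of the spike amplitude, included
specifically to exercise the notch.

*Suppression dynamics.* A normalised drive `h(t) = N(t)/(N(t)+N_1/2)` of
the spike count in the trailing 50 ms engages within one sample and
relaxes as `s(t) = max(h(t), s(t−dt)·e^(−dt/τ_rec))` with τ_rec = 30 ms;
together with the draining of the 50 ms window this yields ≥ 90 % recovery
of release gain within 100 ms of the end of a burst. Release is
`(1 + evoked(t)) · max(1 − a_g · e/(1+e) · s(t), 0)` where `evoked` is a
rectangular plateau (amplitude e = 1 ΔF/F) during matching-sign epochs and
`a_g` is the polarity-group SI amplitude on the measured scale. Because
ΔF/F is referenced to a baseline that contains spontaneous release,
suppression of the spontaneous term makes the *measured* SI exceed the
release-level suppression by the factor (1+e)/e — this is the mechanism
that produces SI > 1.

*Indicator and readout.* Release is filtered by a single-exponential
indicator kernel with τ = 40 ms, averaged over each frame's exposure
(frame timestamps mark the end of exposure), scaled to camera counts and
read out with additive Gaussian noise (0.1 ΔF/F), optionally AR(1).
The fast τ is consistent with suppression onset and recovery being visible
within one or two 50 ms frames and places the most negative
spike-fluorescence cross-correlation at a one-frame (50 ms) delay; slower
kernels (≥ 80 ms) move that extremum to two frames and smear the evoked
onset over several frames.

*Movies.* Each synapse is a Gaussian blob (σ = 1.5 px) on a static
background with per-pixel Poisson noise; ground-truth masks (2σ disks on a
disjoint grid) are written alongside.

*Calibration.* The group amplitudes (posterior 1.63, anterior 0.69), bout
statistics and spike rate above were calibrated so that the **full
pipeline** — including segmentation, ΔF/F and classification — reproduces
the study conditions: the 16/16 versus 13/25 contingency, group-mean SI
near 1.20 (posterior) and 0.54 (anterior), and a pooled Hill amplitude
near 1.05 with N_1/2 near 1.1. The pooled asymptote and the group means
are linked through the within-bout spike-count distribution, so the three
values cannot all be matched exactly at once; the preset shades both group
amplitudes uniformly by ~4 %, which puts every headline statistic within
about 3 % of its target (measured over 12 seeds: Hill amplitude
1.04 ± 0.04, N_1/2 1.07 ± 0.16, group means 1.17 ± 0.03 and
0.53 ± 0.01). These constants live in the `paper_default` preset, not in
the analysis code.

## What the benchmarks do and do not show

The generator's synapses are spatially disjoint, drift-free blobs with
stationary noise and a suppression mechanism that *exactly* follows a Hill
function of the windowed spike count. Passing tests therefore demonstrate
that the pipeline recovers known structure faithfully (unbiased SI,
correct lag, calibrated classification) — not that real neuromast movies
segment this cleanly, nor that real suppression is Hill-shaped. Drift
registration is deliberately out of scope (a no-op hook is kept in the
pipeline config); overlapping synapses, photobleaching and z-drift are not
modelled.

Two measured caveats about the three-step classification are worth
stating prominently:

1. **Autocorrelated noise inflates the type-I rate.** With iid frame
   noise the test's empirical size is 0.048 (4000 null synapses). With
   AR(1) noise it rises to 0.055 (ρ = 0.05), 0.060 (ρ = 0.1) and 0.095
   (ρ = 0.3), because coincident frames arrive in bout-length runs and the
   effective sample size shrinks. The familiar argument that weak
   correlations "bias toward the null" applies to *power* (suppression
   leaking into nominally non-coincident neighbouring frames), not to
   *size*. The null preset uses ρ = 0.3 — the lag-1 correlation a 40 ms
   indicator imposes on biological rate noise at 50 ms frames — so the
   package's own acceptance check reports this inflation rather than
   hiding it.
2. **Evoked-response ramps interact with bout placement.** For synapses
   with a stimulus-evoked response, the indicator-limited onset ramp means
   early-epoch frames are systematically dimmer; whether coincident frames
   oversample that ramp depends on where bouts happened to fall, so the
   per-dataset false-suppression rate of *responsive but unaffected*
   synapses fluctuates (0–17 % per dataset observed with iid noise). This
   is intrinsic to the classification itself, not to the generator.

## Numerical choices and degenerate inputs

* The suppression-state recursion is evaluated with a chunked
  cumulative-maximum identity (exact to machine precision against the
  sequential recurrence; chunk size bounded so decay weights cannot
  overflow).
* Cross-correlations are Pearson coefficients per lag on the overlapping
  segments, so |r| ≤ 1 holds exactly; constant inputs raise rather than
  return NaN.
* Constant pixels get neighbour-correlation 0; empty coincident or
  spike-free partitions yield the label *untestable*, never an exception;
  a quiet-trial-free synapse raises at the R_o stage and is reported as
  untestable by the pipeline.
* Mann-Whitney p-values use scipy's exact method for small tie-free
  samples and the corrected normal approximation otherwise.
* All randomness flows from a single seed through named substreams
  (`motor`, `traces`, `movie`, `efferent`), so identical configs give
  byte-identical reports and each stage is individually reproducible.

## Problem sizes

The default preset simulates 180 s recordings (5 kHz nerve, 20 Hz imaging,
96×96 movies, 41 synapses, 56 pressure steps). The acceptance script
averages the Hill fit over 20 independent pipeline runs and the group
means over 10; the lag uses five 120 s spontaneous-release simulations,
and the classification size uses one 1000-synapse null dataset. The test
suite reuses three pipeline runs for the heavier checks.
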