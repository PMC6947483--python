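# lateralline

Quantitative analysis of **efference-copy inhibition in the zebrafish
lateral line**: how motor commands during (fictive) swimming switch off
glutamate release from neuromast hair-cell synapses, measured with
fluorescent indicators (iGluSnFR/GCaMP) while recording the motor nerve.

The package turns raw inputs — a 5 kHz extracellular motor-nerve trace,
20–50 Hz fluorescence movies and a table of pressure-step stimuli — into:

* filtered traces, spike trains, smoothed firing rates and swim **bouts**
  (300–1000 Hz zero-phase band-pass + 50 Hz notch, MAD-based thresholding,
  Gaussian rate kernel with FWHM = 100 ms);
* correlation-seeded **ROI segmentation** of the movies and per-synapse
  ΔF/F traces (baseline F = mean fluorescence of the first 10 s preceding
  the first stimulus);
* per-trial **suppression-index** profiles

  `SI(t) = (R_o(t) − R_m(t)) / R_o(t)`

  where `R_o` is the mean stimulus response without motor activity and
  `R_m` a single trial's response (SI = 0 none, SI = 1 full, SI > 1
  suppression below the pre-stimulus baseline);
* the pooled **Hill gain curve** relating SI to the motor spike count `N_s`
  in the preceding 50 ms,

  `SI(N_s) = SI_max · N_s / (N_s + N_1/2)` ;

* a three-step **suppressed / unaffected classification** per synapse
  (pool in-stimulus frames, partition by spike coincidence, one-tailed
  Mann-Whitney U at α = 0.05);
* **polarity statistics**: group-mean SI of posterior- versus
  anterior-tuned hair cells, a Mann-Whitney group comparison, and the
  binomial null probability `p_overall^n` that all synapses of one
  polarity are suppressed by chance;
* motor-sensory **coupling metrics**: per-bout fluorescence integrals
  versus spike counts and the signed cross-correlogram between a trace and
  the frame-downsampled spike train (suppression lag = lag of the most
  negative correlation).

Because no public dataset exists for this preparation, the package ships a
first-class, ground-truthed **synthetic data generator** (`synthgen`):
bout-structured spiking with variable bout vigour, indicator kinetics,
stimulus-evoked release of two opposing hair-cell polarities, and
spike-count-dependent suppression following the Hill relation above. Every
pipeline stage is tested against this ground truth; the generator's
defaults reproduce the headline study conditions (41 synapses: 16/16
posterior and 13/25 anterior suppressed).

## Worked example

Desk-scale statistics straight from the library:

```python
>>> from lateralline import polarity_binomial_test, hill_predict
>>> round(polarity_binomial_test(0.7, 16), 3)   # all 16 suppressed by chance?
0.003
>>> round(hill_predict((1.05, 1.12), 5), 3)     # SI after a 5-spike burst
0.858
```

The first number is the probability, under a polarity-blind null in which
each synapse is suppressed with probability 0.7, that all 16
posterior-polarity synapses come out suppressed — small enough to reject
the null. The second says a 5-spike burst in the preceding 50 ms predicts
~86 % suppression of the stimulus-evoked response.

Full pipeline on a synthetic dataset (simulation → spike detection → movie
segmentation → ΔF/F → classification → Hill fit → polarity statistics):

```bash
$ lateralline run --preset paper_default --outdir out --seed 1020
$ lateralline report --report out/report.json
synapses: 41  contingency: {'posterior_suppressed': 16, 'posterior_unaffected': 0,
  'posterior_untestable': 0, 'anterior_suppressed': 13, 'anterior_unaffected': 12,
  'anterior_untestable': 0}
suppressed fraction: 0.7073170731707317  binomial null p: 0.00392487887739893
Hill: SI_max=1.0851590302496141 N_1/2=1.1719259052176871
group SI: posterior=1.1983498537856858 anterior=0.5231770013418757 p=5.658190325651859e-06
```

All 16 posterior synapses and 13 of 25 anterior synapses are classified
suppressed (71 %); the pooled Hill fit estimates the maximal suppression
`SI_max` ≈ 1.09 and half-maximal spike count `N_1/2` ≈ 1.2 for this seed
(single-dataset fits scatter noticeably around these values — the
acceptance script averages 20 of them); posterior-tuned synapses are
suppressed about twice as strongly as anterior-tuned ones (group means
≈ 1.20 vs 0.52), a highly significant difference.

Other entry points: `lateralline simulate` (write a synthetic dataset:
TIFF movie, HDF5 ephys, CSV protocol, JSON ground truth),
`lateralline detect-spikes`, `lateralline segment-rois`,
`lateralline compute-si`, `lateralline classify`.

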