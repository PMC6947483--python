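"""Synthetic-data generator: ground truth consistency and reproducibility."""

import numpy as np
import pytest
from pydantic import ValidationError

from lateralline.ephys import SpikeTrain
from lateralline.synthgen import (
    SimConfig,
    instantaneous_si,
    simulate_bouts_and_spikes,
    simulate_motor_recording,
    simulate_movie,
    simulate_stimulus_protocol,
    simulate_synapse_traces,
)


class TestSimConfig:
    def test_paper_default_values(self):
        cfg = SimConfig.paper_default()
        assert cfg.ephys_rate == 5000.0
        assert cfg.frame_rate == 20.0
        assert cfg.si_max_true == 1.05 and cfg.n_half_true == 1.12
        assert cfg.si_mean_posterior == 1.20 and cfg.si_mean_anterior == 0.54
        assert cfg.n_synapses_posterior == 16
        assert cfg.n_synapses_anterior == 25 and cfg.n_anterior_suppressed == 13

    @pytest.mark.parametrize(
        "field, value",
        [("duration", -1.0), ("frame_rate", 10.0), ("n_half_true", 0.0), ("bout_rate", -2.0)],
    )
    def test_invalid_fields_named_in_error(self, field, value):
        with pytest.raises(ValidationError, match=field):
            SimConfig(**{field: value})

    def test_frame_rate_cannot_exceed_ephys_rate(self):
        with pytest.raises(ValidationError, match="frame_rate"):
            SimConfig(ephys_rate=30.0, frame_rate=40.0)

    def test_instantaneous_si_formula(self):
        cfg = SimConfig.paper_default()
        assert instantaneous_si(cfg, 5) == pytest.approx(1.05 * 5 / 6.12, abs=1e-9)
        assert instantaneous_si(cfg, 5) == pytest.approx(0.858, abs=1e-3)
        assert instantaneous_si(cfg, 0) == 0.0


class TestMotorRecording:
    def test_zero_bout_rate_gives_noise_only(self):
        cfg = SimConfig(duration=10.0, bout_rate=0.0, mains_amplitude=0.0, seed=1)
        trace, gt = simulate_motor_recording(cfg)
        assert gt.spike_times.size == 0
        assert np.abs(trace.samples).max() < 1.0  # no spike template anywhere

    def test_sampling_rate_header(self):
        trace, _ = simulate_motor_recording(SimConfig.paper_default(duration=2.0))
        assert trace.rate == 5000.0

    def test_mean_spikes_per_bout_matches_generating_process(self):
        """With refractory off, E[spikes/bout] = rate x mean duration = 20;
        checked against the closed form within 3 empirical SEs."""
        counts = []
        for seed in range(20):
            cfg = SimConfig(
                duration=300.0, bout_rate=0.1, bout_duration_mean=0.5,
                within_bout_spike_rate=40.0, refractory=0.0, seed=seed,
            )
            _, bouts = simulate_bouts_and_spikes(cfg, cfg.rng("motor"))
            counts.extend(b[2] for b in bouts)
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 20.0) <= 3 * se

    def test_spike_times_strictly_increasing_and_in_range(self):
        for seed in range(5):
            cfg = SimConfig(duration=30.0, seed=seed)
            _, gt = simulate_motor_recording(cfg)
            st = gt.spike_times
            assert np.all(np.diff(st) > 0)
            assert st.size == 0 or (st[0] >= 0 and st[-1] <= cfg.duration)

    def test_seed_reproducibility(self):
        cfg = SimConfig(duration=20.0, seed=42)
        a, gta = simulate_motor_recording(cfg)
        b, gtb = simulate_motor_recording(cfg)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(gta.spike_times, gtb.spike_times)


class TestStimulusProtocol:
    def test_empty_protocol(self):
        assert simulate_stimulus_protocol(SimConfig(n_steps=0)) == []

    def test_signs_alternate(self):
        epochs = simulate_stimulus_protocol(SimConfig(n_steps=4))
        assert [e.sign for e in epochs] == [1, -1, 1, -1]

    def test_epochs_pairwise_disjoint(self):
        epochs = simulate_stimulus_protocol(SimConfig.paper_default())
        for a, b in zip(epochs, epochs[1:]):
            assert a.offset <= b.onset


class TestSynapseTraces:
    def test_suppression_disabled_means_zero_true_si(self):
        cfg = SimConfig.null(duration=40.0, noise_ar=0.0, evoked_dff=1.0, seed=2)
        _, gt = simulate_motor_recording(cfg)
        spikes = SpikeTrain(gt.spike_times, cfg.ephys_rate)
        epochs = simulate_stimulus_protocol(cfg)
        _, gt2 = simulate_synapse_traces(cfg, spikes, epochs)
        assert np.allclose(gt2.noiseless_dff, gt2.unsuppressed_dff)

    def test_gain_recovers_within_100ms(self):
        """After a burst ends, the release gain is back to >= 90% of its
        unsuppressed value 100 ms later."""
        cfg = SimConfig(duration=6.0, n_steps=0, seed=0)
        burst = np.arange(2.0, 2.5, 0.005)
        spikes = SpikeTrain(burst, cfg.ephys_rate)
        traces, gt = simulate_synapse_traces(cfg, spikes, [])
        s = gt.si_state_frames
        t = gt.frame_times
        # suppression state scaled to the strongest (posterior) synapse
        rel = cfg.si_amp_posterior * cfg.evoked_dff / (1 + cfg.evoked_dff)
        # first frame fully after burst end + 100 ms (state only decays there)
        gain_at = 1.0 - rel * s[np.searchsorted(t, 2.5 + 0.1) + 1]
        assert gain_at >= 0.9

    def test_clock_mismatch_rejected(self):
        cfg = SimConfig(duration=5.0)
        spikes = SpikeTrain(np.array([10.0]), cfg.ephys_rate)  # beyond duration
        with pytest.raises(ValueError, match="duration"):
            simulate_synapse_traces(cfg, spikes, [])

    def test_reproducible_and_polarity_layout(self):
        cfg = SimConfig(duration=30.0, seed=9)
        _, gt = simulate_motor_recording(cfg)
        spikes = SpikeTrain(gt.spike_times, cfg.ephys_rate)
        epochs = simulate_stimulus_protocol(cfg)
        tr1, gta = simulate_synapse_traces(cfg, spikes, epochs)
        tr2, _ = simulate_synapse_traces(cfg, spikes, epochs)
        assert all(np.array_equal(a.values, b.values) for a, b in zip(tr1, tr2))
        assert gta.polarity.count("posterior") == cfg.n_synapses_posterior
        assert sum(gta.suppressed) == cfg.n_synapses_posterior + cfg.n_anterior_suppressed


class TestMovie:
    def test_shape_contract(self):
        cfg = SimConfig.tiny(duration=5.0, frame_height=64, frame_width=64)
        ft = np.arange(1, 101) / 20.0
        from lateralline.imaging import FluoTrace

        traces = [FluoTrace(values=np.full(100, 100.0), frame_times=ft) for _ in range(2)]
        movie, _ = simulate_movie(cfg, traces)
        assert movie.pixels.shape == (100, 64, 64)
        assert movie.pixels.dtype == np.uint16

    def test_background_only_is_flat(self):
        cfg = SimConfig.tiny(duration=5.0, blob_amplitude=1e-9, shot_noise=False)
        ft = np.arange(1, 101) / 20.0
        from lateralline.imaging import FluoTrace

        rng = np.random.default_rng(0)
        traces = [
            FluoTrace(values=100 + 50 * rng.normal(size=100), frame_times=ft)
            for _ in range(2)
        ]
        movie, _ = simulate_movie(cfg, traces)
        mean_series = movie.pixels.mean(axis=(1, 2))
        assert mean_series.std() <= 0.5  # flat within rounding noise

    def test_noiseless_extraction_recovers_trace(self):
        cfg = SimConfig.tiny(duration=20.0, shot_noise=False, noise_sd=0.0, seed=3)
        _, gt = simulate_motor_recording(cfg)
        spikes = SpikeTrain(gt.spike_times, cfg.ephys_rate)
        epochs = simulate_stimulus_protocol(cfg)
        traces, _ = simulate_synapse_traces(cfg, spikes, epochs)
        movie, gtm = simulate_movie(cfg, traces)
        for m, tr in zip(gtm.roi_masks, traces):
            # mask-average recomputed independently of extract_traces
            vals = movie.pixels[:, m.pixels[:, 0], m.pixels[:, 1]].mean(axis=1)
            assert np.corrcoef(vals, tr.values)[0, 1] > 0.99

    def test_masks_disjoint(self):
        cfg = SimConfig.paper_default(duration=2.0)
        ft = np.arange(1, 41) / 20.0
        from lateralline.imaging import FluoTrace

        traces = [FluoTrace(values=np.full(40, 100.0), frame_times=ft) for _ in range(cfg.n_synapses)]
        _, gt = simulate_movie(cfg, traces)
        seen = set()
        for m in gt.roi_masks:
            pix = set(map(tuple, m.pixels))
            assert not pix & seen
            seen |= pix

    def test_too_many_blobs_rejected(self):
        cfg = SimConfig.tiny(duration=5.0, frame_height=16, frame_width=16)
        cfg = cfg.model_copy(update={"n_synapses_posterior": 30})
        ft = np.arange(1, 11) / 20.0
        from lateralline.imaging import FluoTrace

        traces = [FluoTrace(values=np.full(10, 1.0), frame_times=ft) for _ in range(31)]
        with pytest.raises(ValueError, match="blobs"):
            simulate_movie(cfg, traces)
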