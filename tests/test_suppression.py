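"""Suppression-index statistics, Hill fitting, classification, polarity tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lateralline.ephys import SpikeTrain
from lateralline.imaging import FluoTrace
from lateralline.suppression import (
    StimulusEpoch,
    Trial,
    TrialSet,
    build_trial_set,
    classify_synapse,
    compare_polarity_groups,
    compute_si_profiles,
    fit_hill,
    hill_predict,
    mean_quiet_response,
    polarity_binomial_test,
    pool_si_vs_spikes,
    suppression_index,
    synapse_mean_si,
)

FR = 20.0


def _dff(values):
    v = np.asarray(values, dtype=float)
    return FluoTrace(
        values=v, frame_times=np.arange(1, v.size + 1) / FR, baseline_F=1.0, units="dff"
    )


def _make_trial(values, coincident, quiet=None, n_s=None):
    values = np.asarray(values, dtype=float)
    coincident = np.asarray(coincident, dtype=int)
    return Trial(
        epoch=StimulusEpoch(0.0, values.size / FR + 0.1, 1),
        values=values,
        frame_times=np.arange(1, values.size + 1) / FR,
        n_s=coincident if n_s is None else np.asarray(n_s),
        frame_counts=coincident,
        quiet=bool(coincident.sum() == 0) if quiet is None else quiet,
    )


class TestBuildTrialSet:
    def test_epoch_frame_counting(self):
        """A 1 s epoch at 20 Hz gives 20 in-epoch frames minus the dropped
        first one = 19."""
        tr = _dff(np.zeros(400))
        epochs = [StimulusEpoch(5.0, 6.0, 1)]
        ts = build_trial_set(tr, epochs, SpikeTrain(np.empty(0), 5000.0), "posterior")
        assert len(ts.trials) == 1
        assert ts.trials[0].values.size == 19

    def test_spikeless_recording_all_quiet(self):
        tr = _dff(np.zeros(400))
        epochs = [StimulusEpoch(3.0, 4.0, 1), StimulusEpoch(6.0, 7.0, 1)]
        ts = build_trial_set(tr, epochs, SpikeTrain(np.empty(0), 5000.0), "posterior")
        assert all(t.quiet for t in ts.trials)
        assert all(np.all(t.n_s == 0) for t in ts.trials)

    def test_window_counts_match_brute_force(self, rng):
        tr = _dff(np.zeros(400))
        epochs = [StimulusEpoch(3.0, 4.0, 1), StimulusEpoch(9.0, 10.0, 1)]
        spikes = SpikeTrain(np.sort(rng.uniform(0, 20, 300)), 5000.0)
        ts = build_trial_set(tr, epochs, spikes, "posterior", ns_window=0.05)
        for t in ts.trials:
            for f, n in zip(t.frame_times, t.n_s):
                assert n == np.sum((spikes.times > f - 0.05) & (spikes.times <= f))

    def test_wrong_polarity_epochs_rejected(self):
        tr = _dff(np.zeros(200))
        with pytest.raises(ValueError, match="polarity|sign"):
            build_trial_set(
                tr, [StimulusEpoch(3.0, 4.0, -1)], SpikeTrain(np.empty(0), 5000.0), "posterior"
            )


class TestMeanQuietResponse:
    def test_identical_quiet_trials(self):
        seg = np.linspace(0, 1, 19)
        ts = TrialSet(0, "posterior", [_make_trial(seg, np.zeros(19)) for _ in range(4)])
        r_o, sem = mean_quiet_response(ts)
        assert np.allclose(r_o, seg)

    def test_sem_scales_as_sampling_theory(self, rng):
        """SE of the quiet mean ~ sigma/sqrt(n) over repeated draws."""
        sigma, n = 0.2, 8
        sems = []
        for _ in range(200):
            trials = [
                _make_trial(1.0 + rng.normal(0, sigma, 19), np.zeros(19))
                for _ in range(n)
            ]
            _, sem = mean_quiet_response(TrialSet(0, "posterior", trials))
            sems.append(np.mean(sem))
        assert np.mean(sems) == pytest.approx(sigma / np.sqrt(n), rel=0.1)

    def test_no_quiet_trials_raises(self):
        ts = TrialSet(0, "posterior", [_make_trial(np.ones(19), np.ones(19))])
        with pytest.raises(ValueError, match="quiet"):
            mean_quiet_response(ts)


class TestSuppressionIndex:
    @pytest.mark.parametrize(
        "r_o, r_m, expected",
        [
            (1.0, 1.0, 0.0),    # R_m = R_o: no suppression
            (1.0, 0.0, 1.0),    # full suppression of the evoked response
            (1.0, -0.2, 1.2),   # below pre-stimulus baseline
            (1.0, 1.5, -0.5),   # response larger during motor activity
        ],
    )
    def test_identities(self, r_o, r_m, expected):
        si, valid = suppression_index(np.full(5, r_o), np.full(5, r_m), floor=0.1)
        assert np.all(valid)
        assert si == pytest.approx(np.full(5, expected))

    def test_floor_guards_division(self):
        si, valid = suppression_index(
            np.array([1.0, 0.01, 2.0]), np.zeros(3), floor=0.1
        )
        assert valid.tolist() == [True, False, True]
        assert np.isnan(si[1])

    def test_all_below_floor_raises(self):
        with pytest.raises(ValueError, match="guard|floor|frames"):
            suppression_index(np.full(5, 0.01), np.zeros(5), floor=0.1)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        r_o = rng.uniform(0.5, 2.0, 20)
        r_m = rng.uniform(-0.5, 2.0, 20)
        a, _ = suppression_index(r_o, r_m, floor=0.1)
        b, _ = suppression_index(scale * r_o, scale * r_m, floor=0.1 * scale)
        assert np.allclose(a, b, rtol=1e-9)


class TestPoolAndFit:
    def test_single_profile_pool(self):
        ts = TrialSet(0, "posterior", [_make_trial(np.ones(19) + 1e-3, np.zeros(19))] * 3)
        pooled = pool_si_vs_spikes(compute_si_profiles(ts, floor=0.1))
        assert pooled.index.tolist() == [0]
        assert pooled.loc[0, "mean"] == pytest.approx(0.0, abs=1e-2)

    def test_grouped_means_match_brute_force(self, rng):
        ts_trials = [
            _make_trial(1.0 + rng.normal(0, 0.05, 19), np.zeros(19, dtype=int))
            for _ in range(2)
        ]
        for _ in range(6):
            ns = rng.integers(0, 6, 19)
            vals = 1.0 - 0.1 * ns + rng.normal(0, 0.05, 19)
            ts_trials.append(_make_trial(vals, (ns > 0).astype(int), n_s=ns))
        ts = TrialSet(0, "posterior", ts_trials)
        profiles = compute_si_profiles(ts, floor=0.05)
        pooled = pool_si_vs_spikes(profiles)
        # brute force group-by over the same (n_s, si) pairs
        ns_all = np.concatenate([p.n_s[p.valid] for p in profiles])
        si_all = np.concatenate([p.si[p.valid] for p in profiles])
        for n in np.unique(ns_all):
            assert pooled.loc[n, "mean"] == pytest.approx(si_all[ns_all == n].mean())
            assert pooled.loc[n, "count"] == np.sum(ns_all == n)

    def test_exact_hill_recovery(self):
        n = np.repeat(np.arange(0, 11), 5).astype(float)
        si = 1.05 * n / (n + 1.12)
        fit = fit_hill(n, si)
        assert fit.si_max == pytest.approx(1.05, abs=1e-4)
        assert fit.n_half == pytest.approx(1.12, abs=1e-4)
        assert hill_predict(fit, 5) == pytest.approx(0.858, abs=1e-3)

    def test_hill_predict_identities(self):
        fit = (1.05, 1.12)
        assert hill_predict(fit, 0) == 0.0
        assert hill_predict(fit, 1.12) == pytest.approx(1.05 / 2)
        n = np.arange(0, 200, dtype=float)
        curve = hill_predict(fit, n)
        assert np.all(np.diff(curve) > 0)  # strictly increasing
        assert np.all(curve < 1.05)        # bounded by the asymptote

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_hill(np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 0.5]))


class TestClassifySynapse:
    def _synth_trial_set(self, rng, si=1.0, n_trials=12, noise=0.1, rho=0.0):
        """Stimulus trials with bout-like coincident runs; response 1.0,
        suppressed by ``si`` during coincident frames."""
        trials = []
        for _ in range(n_trials):
            coin = np.zeros(19, dtype=int)
            if rng.uniform() < 0.5:  # a bout overlaps this trial
                start = rng.integers(0, 14)
                coin[start : start + rng.integers(3, 8)] = 1
            eps = rng.normal(0, 1.0, 19)
            if rho > 0:
                for i in range(1, 19):
                    eps[i] = rho * eps[i - 1] + np.sqrt(1 - rho**2) * eps[i]
            vals = 1.0 - si * coin + noise * eps
            trials.append(_make_trial(vals, coin))
        return TrialSet(0, "posterior", trials)

    def test_no_motor_spikes_is_untestable(self):
        ts = TrialSet(0, "posterior", [_make_trial(np.ones(19), np.zeros(19))] * 5)
        assert classify_synapse(ts).label == "untestable"

    def test_power_on_fully_suppressed_synapse(self, rng):
        """A synapse with true SI = 1 under default noise is detected in
        >= 90% of 200 replicates."""
        hits = sum(
            classify_synapse(self._synth_trial_set(rng, si=1.0)).label == "suppressed"
            for _ in range(200)
        )
        assert hits >= 180

    def test_size_under_independence(self, rng):
        """Type-I rate <= alpha on iid null trial sets (1000 replicates)."""
        false = sum(
            classify_synapse(self._synth_trial_set(rng, si=0.0)).label == "suppressed"
            for _ in range(1000)
        )
        assert false <= 60  # 5% of 1000 plus binomial slack

    def test_mann_whitney_matches_enumeration(self, rng):
        """scipy's exact one-sided p equals brute-force enumeration of all
        group assignments on a small instance."""
        x = rng.normal(size=4)   # 'coincident'
        y = rng.normal(size=5) + 0.5
        res = stats.mannwhitneyu(x, y, alternative="less", method="exact")
        combined = np.concatenate([x, y])
        u_obs = stats.mannwhitneyu(x, y, alternative="less").statistic
        count = total = 0
        for idx in itertools.combinations(range(9), 4):
            xs = combined[list(idx)]
            ys = np.delete(combined, list(idx))
            u = stats.mannwhitneyu(xs, ys, alternative="less").statistic
            count += u <= u_obs
            total += 1
        assert res.pvalue == pytest.approx(count / total, abs=1e-12)


class TestPolarityStatistics:
    def test_binomial_null_probability(self):
        assert round(polarity_binomial_test(0.7, 16), 3) == 0.003
        assert polarity_binomial_test(0.3, 0) == 1.0
        assert polarity_binomial_test(1.0, 99) == 1.0

    def test_identical_groups_not_significant(self):
        g = list(np.linspace(0.2, 1.4, 10))
        cmp = compare_polarity_groups(g, g)
        assert cmp.p_value > 0.05

    def test_power_at_printed_group_statistics(self, rng):
        """Groups drawn at the printed means/SEMs (1.20+-0.03 n=16 vs
        0.54+-0.07 n=13) separate at p < 0.001 in >= 95% of 500 draws."""
        hits = 0
        for _ in range(500):
            post = rng.normal(1.20, 0.03 * np.sqrt(16), size=16)
            ant = rng.normal(0.54, 0.07 * np.sqrt(13), size=13)
            if compare_polarity_groups(post, ant).p_value < 0.001:
                hits += 1
        assert hits >= 475

    def test_single_element_groups_computable(self):
        cmp = compare_polarity_groups([1.2], [0.5])
        assert 0.0 < cmp.p_value <= 1.0
        assert cmp.low_n

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_polarity_groups([], [1.0])


class TestSynapseMeanSi:
    def test_statistics(self):
        ns = np.array([0, 1, 2, 0, 3])
        si = np.array([0.1, 0.5, 0.7, 0.0, 0.9])
        from lateralline.suppression import SIProfile

        p = SIProfile(r_o=np.ones(5), r_m=np.ones(5), si=si, n_s=ns, valid=np.ones(5, bool))
        assert synapse_mean_si([p], "mean_si") == pytest.approx(np.mean([0.5, 0.7, 0.9]))
        assert synapse_mean_si([p], "max_si") == pytest.approx(0.9)
        assert np.isnan(synapse_mean_si([], "mean_si"))
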