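import math

import numpy as np
import pytest
from scipy import stats as sst

from crowdeda.synthdata import (CohortSpec, ConditionSpec, ScrKernel,
                                SubjectProfile, inject_artifacts,
                                poisson_event_times, scr_kernel_response,
                                simulate_cohort, simulate_recording)


class TestKernel:
    def test_starts_at_zero_and_is_nonnegative(self):
        h = scr_kernel_response(ScrKernel(), fs=32, duration=16)
        assert h[0] == 0.0
        assert (h >= 0).all()
        assert h[-1] < 1e-3 * h.max()

    def test_argmax_matches_closed_form(self):
        k = ScrKernel(tau_rise=0.7, tau_decay=2.0)
        fs = 1000.0
        h = scr_kernel_response(k, fs=fs, duration=16)
        t_star = (k.tau_rise * k.tau_decay / (k.tau_decay - k.tau_rise)
                  * math.log(k.tau_decay / k.tau_rise))
        assert np.argmax(h) / fs == pytest.approx(t_star, abs=2 / fs)
        assert k.peak_lag == pytest.approx(t_star)

    def test_gain_scales_linearly(self):
        h1 = scr_kernel_response(ScrKernel(gain=1.0), fs=32, duration=10)
        h2 = scr_kernel_response(ScrKernel(gain=2.0), fs=32, duration=10)
        np.testing.assert_allclose(h2, 2 * h1)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            ScrKernel(tau_rise=2.0, tau_decay=0.7)

    def test_normalized_kernel_peaks_at_one(self):
        k = ScrKernel().normalized()
        h = scr_kernel_response(k, fs=256, duration=16)
        assert h.max() == pytest.approx(1.0, abs=1e-4)


class TestEventTimes:
    def test_spacing_respected(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = poisson_event_times(0.2, 60.0, rng, min_spacing=3.0)
            if t.size > 1:
                assert np.diff(t).min() >= 3.0

    def test_count_is_poisson_chi_square(self):
        """Counts over many seeds follow Poisson(rate*duration)."""
        rate, dur = 0.05, 100.0
        counts = []
        for s in range(600):
            rng = np.random.default_rng(s)
            counts.append(poisson_event_times(rate, dur, rng).size)
        counts = np.asarray(counts)
        mu = rate * dur
        kmax = 12
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = sst.poisson.pmf(np.arange(kmax), mu) * counts.size
        expected = np.append(expected, counts.size - expected.sum())
        keep = expected > 1
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sst.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01


class TestSimulateRecording:
    def test_all_stochastic_parts_off_gives_constant(self):
        profile = SubjectProfile(baseline_scl=4.2, drift_slope=0.0,
                                 scr_rate=0.0, noise_sd=0.0)
        rec, gt = simulate_recording(profile, [ConditionSpec("a", 30.0)],
                                     seed=1)
        np.testing.assert_allclose(rec.eda, 4.2)
        np.testing.assert_allclose(gt.tonic, 4.2)

    def test_noise_and_rate_off_equals_ground_truth_tonic(self):
        profile = SubjectProfile(baseline_scl=5.0, drift_slope=0.01,
                                 scr_rate=0.0, noise_sd=0.0)
        schedule = [ConditionSpec("a", 30.0), ConditionSpec("b", 30.0, 2.0)]
        rec, gt = simulate_recording(profile, schedule, seed=1)
        np.testing.assert_array_equal(rec.eda, gt.tonic)

    def test_event_count_monte_carlo_matches_poisson_mean(self):
        rate, dur, n_seeds = 0.1, 300.0, 200
        profile = SubjectProfile(scr_rate=rate, noise_sd=0.0)
        total = 0
        for s in range(n_seeds):
            _, gt = simulate_recording(profile, [ConditionSpec("a", dur)],
                                       seed=s)
            total += len(gt.events)
        mean = total / n_seeds
        mu = rate * dur
        assert abs(mean - mu) < 3 * math.sqrt(mu) / math.sqrt(n_seeds)

    def test_same_seed_bit_identical(self):
        profile = SubjectProfile()
        a, _ = simulate_recording(profile, [ConditionSpec("a", 20.0)], seed=9)
        b, _ = simulate_recording(profile, [ConditionSpec("a", 20.0)], seed=9)
        np.testing.assert_array_equal(a.eda, b.eda)
        np.testing.assert_array_equal(a.acc, b.acc)

    def test_condition_offset_moves_tonic_exactly(self):
        profile = SubjectProfile(baseline_scl=6.0, drift_slope=0.0,
                                 scr_rate=0.0, noise_sd=0.0)
        schedule = [ConditionSpec("A", 30.0, 0.0),
                    ConditionSpec("B", 30.0, 2.0)]
        rec, gt = simulate_recording(profile, schedule, seed=0)
        a = rec.eda[:960].mean()
        b = rec.eda[960:].mean()
        assert b - a == pytest.approx(2.0, abs=1e-12)


class TestInjectArtifacts:
    def test_dropout_zeroes_interval(self, noisy_recording):
        out, truth = inject_artifacts(noisy_recording,
                                      [("dropout", (10.0, 15.0))], seed=0)
        np.testing.assert_array_equal(out.eda[320:480], 0.0)
        assert truth[0].kind == "dropout"
        # accelerometer burst accompanies the dropout
        assert out.acc[320:480].mean() > noisy_recording.acc.mean() + 1.0

    def test_no_artifacts_is_identity(self, noisy_recording):
        out, truth = inject_artifacts(noisy_recording, [], seed=0)
        np.testing.assert_array_equal(out.eda, noisy_recording.eda)
        assert truth == []

    def test_spike_has_one_sample_slope_of_160(self, flat_recording):
        out, _ = inject_artifacts(flat_recording, [("spike", (2.0, 3.0))],
                                  seed=0, spike_amplitude=5.0)
        slope = np.abs(np.diff(out.eda)) * flat_recording.fs
        assert slope.max() == pytest.approx(160.0)

    def test_overlapping_intervals_rejected(self, noisy_recording):
        with pytest.raises(ValueError, match="overlap"):
            inject_artifacts(noisy_recording,
                             [("dropout", (10.0, 15.0)),
                              ("spike", (14.0, 16.0))], seed=0)


class TestSimulateCohort:
    def test_counts(self, small_cohort_spec):
        cohort = simulate_cohort(small_cohort_spec)
        assert len(cohort.recordings) == 3
        assert len(cohort.markers) == 9
        assert len(cohort.truth) == 9

    def test_planted_offset_recovered_exactly_without_noise(self):
        conditions = (ConditionSpec("A", 30.0, 0.0, 0.0),
                      ConditionSpec("B", 30.0, 2.0, 0.0))
        spec = CohortSpec(n_subjects=4, conditions=conditions, seed=3,
                          noise_sd=0.0, scr_rate=0.0, drift_slope_sd=0.0,
                          subject_effect_sd=0.0)
        cohort = simulate_cohort(spec)
        wide = cohort.truth.pivot(index="subject_id", columns="label",
                                  values="true_mean_tonic")
        np.testing.assert_allclose(wide["B"] - wide["A"], 2.0, atol=1e-12)

    def test_between_subject_variance_nonzero(self, small_cohort_spec):
        cohort = simulate_cohort(small_cohort_spec)
        base = cohort.truth[cohort.truth.label == "baseline"]
        assert base["true_mean_tonic"].std() > 0.1

    def test_seed_determinism(self, small_cohort_spec):
        a = simulate_cohort(small_cohort_spec)
        b = simulate_cohort(small_cohort_spec)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.eda, rb.eda)
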