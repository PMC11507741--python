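"""Truncation sweeps: truth conventions, SSE decay fit, recovery studies."""

import numpy as np
import pytest

import steinshrink as ss


class TestDecayFit:
    def test_exact_exponential_recovered(self):
        n = np.array([15, 25, 50, 90])
        fit = ss.fit_sse_decay(n, 4.0 * np.exp(-0.05 * n))
        assert fit.amplitude == pytest.approx(4.0, rel=1e-10)
        assert fit.rate == pytest.approx(0.05, rel=1e-10)

    def test_constant_sse_has_zero_rate(self):
        fit = ss.fit_sse_decay([10, 20, 30, 40], [2.0, 2.0, 2.0, 2.0])
        assert fit.rate == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitude == pytest.approx(2.0)

    def test_matches_brute_force_grid_search(self):
        """The log-linear fit attains the minimum of the squared
        log-residual objective found by a dense two-parameter grid search."""
        rng = np.random.default_rng(4)
        n = np.arange(10, 60, 5)
        sse = 3.0 * np.exp(-0.04 * n) * np.exp(rng.normal(0, 0.2, n.size))
        fit = ss.fit_sse_decay(n, sse)

        def loss(amp, rate):
            return ((np.log(sse) - (np.log(amp) - rate * n)) ** 2).sum()

        amps = np.linspace(0.5, 8.0, 301)
        rates = np.linspace(0.0, 0.1, 301)
        grid_losses = np.array([[loss(a, r) for r in rates] for a in amps])
        i, j = np.unravel_index(grid_losses.argmin(), grid_losses.shape)
        assert loss(fit.amplitude, fit.rate) <= grid_losses[i, j] + 1e-9
        assert fit.amplitude == pytest.approx(amps[i], abs=np.diff(amps)[0])
        assert fit.rate == pytest.approx(rates[j], abs=np.diff(rates)[0])

    def test_nonpositive_sse_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            fit = ss.fit_sse_decay([10, 20, 30, 40], [1.0, 0.0, 0.5, 0.25])
        assert fit.n_points_used == 3
        with pytest.raises(ValueError, match="at least 3"):
            with pytest.warns(UserWarning):
                ss.fit_sse_decay([10, 20, 30], [1.0, 0.0, 0.0])


class TestSweepSpec:
    def test_defaults_fill_grid_and_truth(self):
        spec = ss.SweepSpec(dataset_kind="resting_metabolic")
        assert spec.truncation_grid == tuple(range(10, 36, 3))
        assert spec.truth_size == 40

    def test_grid_must_increase_and_stay_below_truth(self):
        with pytest.raises(ValueError, match="increasing"):
            ss.SweepSpec(dataset_kind="kinematic",
                         truncation_grid=(20, 15), truth_size=100)
        with pytest.raises(ValueError, match="below truth_size"):
            ss.SweepSpec(dataset_kind="kinematic",
                         truncation_grid=(15, 100), truth_size=100)


class TestRunSweep:
    def test_zero_noise_gives_zero_error_everywhere(self):
        spec = ss.default_kinematic_spec(seed=1, step_noise_sd=0.0)
        trials, _ = ss.simulate_kinematic_cohort(spec)
        res = ss.run_sweep(trials, ss.SweepSpec(dataset_kind="kinematic"))
        np.testing.assert_allclose(res.sse_mle, 0.0, atol=1e-18)
        np.testing.assert_allclose(res.sse_jse, 0.0, atol=1e-18)
        np.testing.assert_allclose(res.applied_c, 1.0)
        if res.decay_fit is not None:  # float residue can leave SSE ~1e-30
            assert res.decay_fit.amplitude < 1e-20

    def test_short_participant_named(self, kinematic_cohort):
        trials, _ = kinematic_cohort
        short = ss.KinematicTrial("PXX", *(np.zeros(50) for _ in range(5)))
        with pytest.raises(ValueError, match="PXX"):
            ss.run_sweep(list(trials) + [short],
                         ss.SweepSpec(dataset_kind="kinematic"))

    def test_truth_proxy_artifact_near_truth_size(self, kinematic_cohort):
        """With a finite-truth proxy, grid values near the truth size can
        show negative percent reduction — truth noise rivals MLE noise."""
        trials, _ = kinematic_cohort
        res = ss.run_sweep(trials, ss.SweepSpec(dataset_kind="kinematic",
                                                seed=3))
        assert (res.pct_reduction[-6:] < 0).any()
        # while short truncations still benefit clearly
        assert res.pct_reduction[0] > 0

    def test_recovery_mode_uses_generative_truth(self, kinematic_cohort):
        trials, truths = kinematic_cohort
        res = ss.run_sweep(trials, ss.SweepSpec(dataset_kind="kinematic"),
                           truths=truths)
        np.testing.assert_array_equal(
            res.truth_values, [t.true_parameter for t in truths])
        assert res.truth_estimates is None

    def test_full_duration_estimate_converges_to_truth(self):
        """MLE consistency transfers to the sweep's truth proxy: very long
        trials put the full-duration estimate near the generative truth."""
        spec = ss.default_kinematic_spec(seed=6, n_participants=4,
                                         n_steps=20000)
        trials, truths = ss.simulate_kinematic_cohort(spec)
        res = ss.run_sweep(
            trials, ss.SweepSpec(dataset_kind="kinematic",
                                 truncation_grid=(100, 200, 400),
                                 truth_size=20000))
        gen = np.array([t.true_parameter for t in truths])
        np.testing.assert_allclose(res.truth_values, gen, atol=5e-3)

    def test_summary_and_tidy_frames(self, resting_cohort):
        trials, _ = resting_cohort
        spec = ss.SweepSpec(dataset_kind="resting_metabolic", n_boot=150)
        res = ss.run_sweep(trials, spec)
        summary = res.summary_frame()
        assert len(summary) == len(spec.truncation_grid) + 1
        assert summary["is_truth"].sum() == 1
        tidy = res.tidy_frame()
        assert len(tidy) == len(spec.truncation_grid) * len(trials)
        assert set(tidy.columns) >= {"n", "participant_id", "y_mle",
                                     "z_jse", "x_truth"}


class TestRecoveryStudy:
    def test_single_replicate_reproducible(self):
        spec = ss.default_kinematic_spec()
        sspec = ss.SweepSpec(dataset_kind="kinematic",
                             truncation_grid=(15, 30, 60), truth_size=100)
        a = ss.recovery_study(spec, sspec, n_reps=1, seed=9)
        b = ss.recovery_study(spec, sspec, n_reps=1, seed=9)
        np.testing.assert_array_equal(a.mean_sse_jse, b.mean_sse_jse)
        np.testing.assert_array_equal(a.mean_applied_c, b.mean_applied_c)

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            ss.recovery_study(ss.default_kinematic_spec(),
                              ss.SweepSpec(dataset_kind="resting_metabolic"),
                              n_reps=1)

    def test_shrinkage_helps_in_expectation(self):
        """Mean SSE of the shrunk estimator stays at or below the MLE's on
        every grid value (kinematic cohort, generative truth)."""
        res = ss.recovery_study(
            ss.default_kinematic_spec(),
            ss.SweepSpec(dataset_kind="kinematic",
                         truncation_grid=(15, 30, 60), truth_size=100),
            n_reps=50, seed=2)
        assert np.all(res.mean_sse_jse <= res.mean_sse_mle)
        assert np.all(res.frac_positive_reduction > 0.5)
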