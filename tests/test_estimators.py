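"""Per-participant estimators: Brockway conversion, foot-placement OLS,
exponential steady-state fit, resting mean, and their error variances."""

import numpy as np
import pytest

import steinshrink as ss


def _random_trial(rng, n_steps=12):
    P = rng.normal(size=(n_steps, 3))
    J = rng.normal(size=(2, 3))
    S = P @ J.T + rng.normal(scale=0.3, size=(n_steps, 2))
    return ss.KinematicTrial("P00", P[:, 0], P[:, 1], P[:, 2],
                             S[:, 0], S[:, 1])


class TestBrockway:
    @pytest.mark.parametrize("vo2, vco2, expected", [
        (0.0, 0.0, 0.0),
        (1.0, 0.0, 16.58),
        (1.0, 1.0, 21.09),
    ])
    def test_known_values(self, vo2, vco2, expected):
        assert ss.brockway_rate(vo2, vco2) == pytest.approx(expected)

    def test_linearity(self, rng):
        vo2 = rng.uniform(0, 1, 50)
        vco2 = rng.uniform(0, 1, 50)
        np.testing.assert_allclose(ss.brockway_rate(2 * vo2, 2 * vco2),
                                   2 * ss.brockway_rate(vo2, vco2))

    def test_negative_input_names_sample(self):
        with pytest.raises(ValueError, match="index 2"):
            ss.brockway_rate([0.1, 0.2, -0.3], [0.1, 0.2, 0.3])


class TestJacobianFit:
    def test_matches_explicit_normal_equations(self, rng):
        """OLS oracle: gains and coefficient variances equal the explicit
        (X'X)^-1 X'Y solution on 100 random small trials."""
        for _ in range(100):
            n = int(rng.integers(8, 30))
            trial = _random_trial(rng, n)
            fit = ss.fit_foot_placement_jacobian(trial)

            X = trial.pelvis_state() - trial.pelvis_state().mean(axis=0)
            Y = trial.foot_placement() - trial.foot_placement().mean(axis=0)
            beta = np.linalg.inv(X.T @ X) @ X.T @ Y
            np.testing.assert_allclose(fit.gain, beta.T, rtol=1e-8)

            resid = Y - X @ beta
            s2 = (resid ** 2).sum(axis=0) / (n - 3)
            expected_var = s2[:, None] * np.diag(np.linalg.inv(X.T @ X))
            np.testing.assert_allclose(fit.coef_variance, expected_var,
                                       rtol=1e-8)

    def test_noiseless_recovery(self, rng):
        P = rng.normal(size=(40, 3))
        J = np.array([[0.4, 0.3, 0.05], [0.0, 0.05, 0.35]])
        S = P @ J.T
        trial = ss.KinematicTrial("P00", P[:, 0], P[:, 1], P[:, 2],
                                  S[:, 0], S[:, 1])
        fit = ss.fit_foot_placement_jacobian(trial)
        np.testing.assert_allclose(fit.gain, J, rtol=1e-10, atol=1e-12)

    def test_uses_first_n_steps_and_window_means(self, rng):
        trial = _random_trial(rng, 60)
        fit = ss.fit_foot_placement_jacobian(trial, 20)
        assert fit.n_steps_used == 20
        np.testing.assert_allclose(
            fit.input_means, trial.pelvis_state()[:20].mean(axis=0))

    def test_constant_column_named(self):
        n = 20
        rng = np.random.default_rng(1)
        trial = ss.KinematicTrial(
            "P00", rng.normal(size=n), np.full(n, 0.5), rng.normal(size=n),
            rng.normal(size=n), rng.normal(size=n))
        with pytest.raises(ValueError, match="vx_pelvis"):
            ss.fit_foot_placement_jacobian(trial)

    def test_too_few_steps_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 7"):
            ss.fit_foot_placement_jacobian(_random_trial(rng, 10), 6)

    def test_reported_variance_calibrated(self):
        """Across 200 participants sharing one true gain matrix, the spread
        of the estimates matches the regression-reported standard error."""
        spec = ss.default_kinematic_spec(
            seed=7, n_participants=200, n_steps=2000,
            population_gain_sd=np.zeros((2, 3)), step_noise_sd=0.01)
        trials, _ = ss.simulate_kinematic_cohort(spec)
        ests = [ss.extract_gain_element(ss.fit_foot_placement_jacobian(tr))
                for tr in trials]
        vals = np.array([e.value for e in ests])
        reported = np.array([e.variance for e in ests])
        assert 0.8 < vals.var(ddof=1) / reported.mean() < 1.25


class TestGainElement:
    def test_field_extraction(self):
        fit = ss.JacobianFit("P01", np.arange(6.0).reshape(2, 3),
                             np.zeros(3), np.zeros(2),
                             0.01 * np.ones((2, 3)), 25)
        pe = ss.extract_gain_element(fit, 1, 1)
        assert (pe.value, pe.variance) == (4.0, 0.01)
        assert pe.n_used == 25

    def test_default_is_sideways_velocity_sensitivity(self):
        gain = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        fit = ss.JacobianFit("P01", gain, np.zeros(3), np.zeros(2),
                             np.zeros((2, 3)), 25)
        # row 0 = x_foot, column 1 = vx_pelvis
        assert ss.extract_gain_element(fit).value == 2.0

    def test_out_of_range_index(self):
        fit = ss.JacobianFit("P01", np.zeros((2, 3)), np.zeros(3),
                             np.zeros(2), np.zeros((2, 3)), 25)
        with pytest.raises(IndexError):
            ss.extract_gain_element(fit, 2, 0)


def _transient_trial(a0, a1, tau, noise_sd=0.0, seed=0, duration=390.0,
                     interval=6.5):
    rng = np.random.default_rng(seed)
    t = np.arange(interval, duration, interval)
    e = a0 + a1 * np.exp(-t / tau) + rng.normal(0, noise_sd, t.size)
    z = np.zeros(t.size)
    return ss.MetabolicTrial("P00", "walking", t, z, z, e)


class TestTransientFit:
    def test_noiseless_recovery(self):
        fit = ss.fit_exponential_transient(_transient_trial(5.0, 3.0, 40.0))
        assert fit.converged
        assert fit.a0 == pytest.approx(5.0, rel=1e-6)
        assert fit.a1 == pytest.approx(3.0, rel=1e-6)
        assert fit.tau == pytest.approx(40.0, rel=1e-6)

    def test_constant_series(self):
        fit = ss.fit_exponential_transient(_transient_trial(2.0, 0.0, 40.0))
        assert fit.a0 == pytest.approx(2.0)
        assert fit.a1 == pytest.approx(0.0, abs=1e-9)

    def test_estimate_sharpens_with_window(self):
        """Median error in a0 decreases with more breaths (100 replicates)."""
        grids = [15, 27, 39, 51]
        errs = {g: [] for g in grids}
        for r in range(100):
            tr = _transient_trial(5.0, -3.5, 30.0, noise_sd=0.3, seed=r)
            for g in grids:
                errs[g].append(abs(ss.fit_exponential_transient(tr, g).a0
                                   - 5.0))
        med = [np.median(errs[g]) for g in grids]
        assert all(b < a for a, b in zip(med, med[1:]))

    def test_too_many_points_rejected(self):
        tr = _transient_trial(5.0, -3.5, 30.0)
        with pytest.raises(ValueError, match="only"):
            ss.fit_exponential_transient(tr, tr.n_breaths + 1)


class TestSteadyState:
    def test_deterministic_given_seed(self):
        tr = _transient_trial(5.0, -3.5, 30.0, noise_sd=0.25, seed=1)
        a = ss.steady_state_estimate(tr, 21, n_boot=150, seed=9)
        b = ss.steady_state_estimate(tr, 21, n_boot=150, seed=9)
        assert (a.value, a.variance) == (b.value, b.variance)

    def test_noiseless_bootstrap_variance_vanishes(self):
        tr = _transient_trial(5.0, -3.5, 30.0)
        est = ss.steady_state_estimate(tr, 30, n_boot=150, seed=2)
        assert est.variance <= 1e-10

    def test_bootstrap_tracks_monte_carlo_spread(self):
        """Typical bootstrap sd of a0 within a factor 1.5 of the fresh-noise
        Monte-Carlo sd.  The median across windows is compared because a
        case-resampled nonlinear refit occasionally produces a heavy-tailed
        variance on an unlucky window."""
        a0s = [ss.fit_exponential_transient(
                   _transient_trial(5.0, -3.5, 30.0, 0.25, seed=1000 + r),
                   21).a0 for r in range(300)]
        mc_sd = np.std(a0s, ddof=1)
        boot_vars = [ss.steady_state_estimate(
                         _transient_trial(5.0, -3.5, 30.0, 0.25, seed=r),
                         21, n_boot=250, seed=r).variance
                     for r in range(15)]
        boot_sd = np.sqrt(np.median(boot_vars))
        assert 1 / 1.5 < boot_sd / mc_sd < 1.5


def _resting_trials(values_per_participant):
    trials = []
    for i, vals in enumerate(values_per_participant):
        vals = np.asarray(vals, dtype=float)
        t = np.arange(1.0, vals.size + 1)
        z = np.zeros(vals.size)
        trials.append(ss.MetabolicTrial(f"P{i:02d}", "resting", t, z, z, vals))
    return trials


class TestRestingMean:
    def test_constant_trials_have_zero_variance(self):
        trials = _resting_trials([np.full(10, 1.3), np.full(10, 1.6),
                                  np.full(10, 1.4), np.full(10, 1.5)])
        for est in ss.resting_mean_estimate(trials, 8, n_boot=200, seed=0):
            assert est.variance <= 1e-12

    def test_pooling_symmetry(self):
        trials = _resting_trials([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        ests = ss.resting_mean_estimate(trials, 3, n_boot=200, seed=0)
        assert [e.value for e in ests] == [1.0, 3.0]
        assert ests[0].variance == ests[1].variance

    def test_pooled_se_matches_closed_form(self):
        """On i.i.d. N(0, s^2) deviations the bootstrap SE^2 of an n-sample
        mean approaches s^2/n."""
        rng = np.random.default_rng(12)
        s, n = 0.4, 20
        trials = _resting_trials(
            [2.0 + rng.normal(0, s, 40) for _ in range(30)])
        ests = ss.resting_mean_estimate(trials, n, n_boot=2000, seed=1)
        assert ests[0].variance == pytest.approx(s ** 2 / n, rel=0.15)

    def test_rejects_walking_trials(self):
        trials = _resting_trials([[1, 1, 1], [2, 2, 2]])
        trials[1] = ss.MetabolicTrial("P01", "walking", trials[1].t,
                                      trials[1].vo2, trials[1].vco2,
                                      trials[1].edot)
        with pytest.raises(ValueError, match="non-resting"):
            ss.resting_mean_estimate(trials, 3)
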