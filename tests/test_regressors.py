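import math

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from fitbench.regressors import (
    ExactGPRegressor,
    KNNUncertaintyRegressor,
    RandomForestUncertaintyRegressor,
    PredictiveDistribution,
    ensemble_mean_variance,
    kernel_eval,
    linear_kernel,
    log_marginal_likelihood,
    matern52_kernel,
    squared_exponential_kernel,
    tune_knn,
    tune_rf,
)
from fitbench.metrics import reduced_chi2


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestKernels:
    def test_zero_distance_returns_signal_variance(self, rng):
        x = rng.standard_normal(4)
        for kind in ("squared_exponential", "matern52"):
            assert kernel_eval(kind, x, x, signal_variance=2.5, lengthscale=0.7) \
                == pytest.approx(2.5)

    def test_matern52_closed_form(self):
        x, xp = np.array([0.0]), np.array([1.5])
        sv, ls = 1.3, 0.8
        r = 1.5
        s = math.sqrt(5) * r / ls
        expected = sv * (1 + s + s**2 / 3) * math.exp(-s)
        assert kernel_eval("matern52", x, xp, sv, ls) == pytest.approx(expected)

    def test_se_vanishes_at_large_distance(self):
        assert kernel_eval("squared_exponential", [0.0], [100.0], 1.0, 1.0) < 1e-300

    def test_linear_scaling(self, rng):
        x, xp = rng.standard_normal(3), rng.standard_normal(3)
        c = 1.7
        assert kernel_eval("linear", c * x, c * xp, 0.9) == \
            pytest.approx(c**2 * kernel_eval("linear", x, xp, 0.9))

    def test_symmetry(self, rng):
        x, xp = rng.standard_normal(5), rng.standard_normal(5)
        for kind in ("linear", "squared_exponential", "matern52"):
            assert kernel_eval(kind, x, xp, 1.2, 0.6) == \
                pytest.approx(kernel_eval(kind, xp, x, 1.2, 0.6))

    def test_gram_psd(self, rng):
        """5-point Gram matrices have eigenvalues >= -1e-10 for every kernel."""
        X = rng.standard_normal((5, 3))
        for K in (linear_kernel(X, X, 1.1),
                  squared_exponential_kernel(X, X, 1.1, 0.9),
                  matern52_kernel(X, X, 1.1, 0.9)):
            assert np.min(np.linalg.eigvalsh(K)) >= -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval("matern52", [0.0, 1.0], [0.0], 1.0, 1.0)

    def test_linear_ard_mode(self, rng):
        X = rng.standard_normal((4, 3))
        sv = np.array([1.0, 2.0, 0.5])
        K = linear_kernel(X, X, sv)
        np.testing.assert_allclose(K, (X * sv) @ X.T)


class TestGP:
    def test_objective_gradient_matches_finite_differences(self, rng):
        from fitbench.regressors import _gram_base

        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        for kern in ("linear", "squared_exponential", "matern52"):
            gp = ExactGPRegressor(kernel=kern)
            base = _gram_base(kern, X)
            z0 = (np.array([0.3, math.log(0.1)]) if kern == "linear"
                  else np.array([0.3, -0.2, math.log(0.1)]))
            num = approx_fprime(z0, lambda z: gp._objective_and_grad(z, base, y)[0], 1e-6)
            ana = gp._objective_and_grad(z0, base, y)[1]
            np.testing.assert_allclose(ana, num, atol=1e-4)

    def test_lml_matches_dense_reimplementation(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        K = matern52_kernel(X, X, 1.3, 0.8)
        nv = 0.2
        Ky = K + nv * np.eye(20)
        dense = (-0.5 * y @ np.linalg.solve(Ky, y)
                 - 0.5 * np.linalg.slogdet(Ky)[1]
                 - 10 * math.log(2 * math.pi))
        assert log_marginal_likelihood(K, y, nv) == pytest.approx(dense, abs=1e-8)

    def test_linear_gp_equals_bayesian_linear_regression(self, rng):
        """Posterior mean matches the closed-form normal equations (n=50, d=5)."""
        n, d = 50, 5
        X = rng.standard_normal((n, d))
        w = rng.standard_normal(d)
        y = X @ w + 0.1 * rng.standard_normal(n)
        sv, nv = 2.0, 0.05
        gp = ExactGPRegressor(kernel="linear", signal_variance=sv, noise_variance=nv,
                              optimize=False, standardize=False).fit(X, y)
        Xs = rng.standard_normal((10, d))
        blr = Xs @ np.linalg.solve(X.T @ X + (nv / sv) * np.eye(d), X.T @ y)
        np.testing.assert_allclose(gp.predict(Xs), blr, atol=1e-6)

    def test_objective_improves_over_initialization(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(40)
        gp = ExactGPRegressor(kernel="squared_exponential", random_state=0).fit(X, y)
        assert gp.objective_ >= gp.initial_objective_

    def test_interpolation_at_low_noise(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0] ** 2
        gp = ExactGPRegressor(kernel="squared_exponential", signal_variance=1.0,
                              lengthscale=1.0, noise_variance=0.01,
                              optimize=False).fit(X, y)
        np.testing.assert_allclose(gp.predict(X), y, atol=0.15)

    def test_duplicate_conflicting_labels_do_not_crash(self):
        X = np.tile(np.array([[1.0, 2.0]]), (6, 1))
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        gp = ExactGPRegressor(kernel="matern52", random_state=0).fit(X, y)
        dist = gp.predict_dist(X)
        assert np.all(np.isfinite(dist.mean))

    def test_stationary_prior_reversion_far_from_data(self, rng):
        """Far from training data a stationary GP reverts to σ² + σ_ε²."""
        X = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        gp = ExactGPRegressor(kernel="matern52", signal_variance=1.5, lengthscale=0.8,
                              noise_variance=0.3, optimize=False,
                              standardize=False).fit(X, y)
        far = gp.predict_dist(np.array([[100.0, 100.0]]))
        assert far.variance[0] == pytest.approx(1.5 + 0.3, rel=1e-6)

    def test_linear_prior_variance_grows_with_norm(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        gp = ExactGPRegressor(kernel="linear", optimize=False,
                              standardize=False).fit(X, y)
        v1 = gp.predict_dist(np.array([[10.0, 0.0, 0.0]])).variance[0]
        v2 = gp.predict_dist(np.array([[100.0, 0.0, 0.0]])).variance[0]
        assert v2 > v1

    def test_predictions_destandardized(self, rng):
        """Labels far from zero are recovered on their original scale."""
        X = rng.standard_normal((40, 2))
        y = 100.0 + 5.0 * X[:, 0] + 0.01 * rng.standard_normal(40)
        gp = ExactGPRegressor(kernel="linear", random_state=0).fit(X, y)
        pred = gp.predict(X)
        assert abs(np.mean(pred) - 100.0) < 1.0

    def test_noise_box_respected(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30) * 10  # heavy noise pushes to the upper bound
        gp = ExactGPRegressor(kernel="squared_exponential", random_state=0).fit(X, y)
        assert 0.01 <= gp.noise_variance_ <= 1.0

    def test_save_load_roundtrip(self, rng, tmp_path):
        X = rng.standard_normal((30, 3))
        y = 2.0 + np.sin(X[:, 0]) + 0.1 * rng.standard_normal(30)
        gp = ExactGPRegressor(kernel="matern52", random_state=0).fit(X, y)
        gp.save(tmp_path / "gp.npz")
        back = ExactGPRegressor.load(tmp_path / "gp.npz")
        Xs = rng.standard_normal((8, 3))
        a, b = gp.predict_dist(Xs), back.predict_dist(Xs)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-10)
        np.testing.assert_allclose(a.variance, b.variance, atol=1e-10)

    def test_errors(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            ExactGPRegressor(kernel="cubic").fit(X, np.zeros(5) + np.arange(5))
        gp = ExactGPRegressor(random_state=0).fit(X, np.arange(5.0))
        with pytest.raises(ValueError):
            gp.predict(rng.standard_normal((3, 4)))  # dimension mismatch


class TestKNN:
    def test_full_neighborhood_is_global_mean(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        dist = KNNUncertaintyRegressor(n_neighbors=10).fit(X, y).predict_dist(X)
        np.testing.assert_allclose(dist.mean, np.full(10, y.mean()))

    def test_single_neighbor(self, rng):
        X = np.arange(5.0).reshape(-1, 1)
        y = np.array([0.0, 1.0, 4.0, 9.0, 16.0])
        dist = KNNUncertaintyRegressor(n_neighbors=1).fit(X, y).predict_dist(
            np.array([[2.1]]))
        assert dist.mean[0] == 4.0
        assert dist.variance[0] == pytest.approx(1e-12)

    def test_tie_broken_by_lowest_index(self):
        X = np.array([[0.0], [2.0], [-2.0]])  # points 1, 2 equidistant from query 0
        y = np.array([5.0, 1.0, 3.0])
        dist = KNNUncertaintyRegressor(n_neighbors=2).fit(X, y).predict_dist(
            np.array([[0.0]]))
        # neighbors: index 0 (d=0) then index 1 (tie with 2, lower index wins)
        assert dist.mean[0] == pytest.approx(3.0)

    def test_variance_is_neighbor_label_variance(self, rng):
        X = np.zeros((4, 1))
        y = np.array([0.0, 2.0, 4.0, 6.0])
        dist = KNNUncertaintyRegressor(n_neighbors=4).fit(X, y).predict_dist(
            np.array([[0.0]]))
        assert dist.variance[0] == pytest.approx(np.var(y))

    def test_default_k(self):
        X = np.arange(9.0).reshape(-1, 1)
        est = KNNUncertaintyRegressor().fit(X, np.arange(9.0))
        assert est.k_ == 3  # ceil(9/3)

    def test_k_out_of_range(self):
        X = np.arange(3.0).reshape(-1, 1)
        with pytest.raises(ValueError):
            KNNUncertaintyRegressor(n_neighbors=4).fit(X, np.arange(3.0))


class TestRandomForest:
    def test_ensemble_variance_formula(self):
        mean, var = ensemble_mean_variance(np.array([[0.0], [2.0]]))
        assert mean[0] == 1.0 and var[0] == 1.0

    def test_agreeing_trees_zero_variance(self):
        mean, var = ensemble_mean_variance(np.full((7, 3), 2.5))
        np.testing.assert_allclose(var, 0.0)

    def test_deterministic_per_seed(self, rng):
        X = rng.standard_normal((40, 3))
        y = X[:, 0] + 0.1 * rng.standard_normal(40)
        a = RandomForestUncertaintyRegressor(n_estimators=20, random_state=1) \
            .fit(X, y).predict(X)
        b = RandomForestUncertaintyRegressor(n_estimators=20, random_state=1) \
            .fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_needs_two_trees(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            RandomForestUncertaintyRegressor(n_estimators=1).fit(X, np.arange(10.0))


class TestPredictiveDistribution:
    def test_contract(self):
        with pytest.raises(ValueError):
            PredictiveDistribution(np.array([1.0]), np.array([-0.1]))
        with pytest.raises(ValueError):
            PredictiveDistribution(np.array([np.nan]), np.array([0.1]))
        with pytest.raises(ValueError):
            PredictiveDistribution(np.array([1.0, 2.0]), np.array([0.1]))


class TestTuning:
    def test_exhaustive_when_range_fits_budget(self, rng):
        """Range <= budget: the returned k is the global internal-CV optimum."""
        X = rng.standard_normal((45, 2))
        y = X[:, 0] + 0.05 * rng.standard_normal(45)
        k = tune_knn(X, y, seed=0, budget=75)
        k_max = int(0.95 * 45 / 3)
        assert 1 <= k <= k_max
        from fitbench.regressors import _internal_cv_mae

        scores = {kk: _internal_cv_mae(
            lambda kk=kk: KNNUncertaintyRegressor(n_neighbors=kk), X, y, 0)
            for kk in range(1, k_max + 1)}
        assert scores[k] == min(scores.values())

    def test_rf_range_contract(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        n_est = tune_rf(X, y, seed=0, budget=5)
        assert 2 <= n_est <= 30

    def test_small_n_falls_back_with_warning(self, rng):
        X = rng.standard_normal((4, 2))
        y = np.arange(4.0)
        with pytest.warns(UserWarning):
            assert tune_knn(X, y, seed=0) == 2  # ceil(4/3)

    def test_tune_inside_fit(self, rng):
        """tune=True picks k by internal CV during fit, on training data only."""
        X = rng.standard_normal((45, 2))
        y = X[:, 0] + 0.05 * rng.standard_normal(45)
        est = KNNUncertaintyRegressor(tune=True, random_state=0).fit(X, y)
        assert est.k_ == tune_knn(X, y, seed=0)

    def test_tuned_beats_default_on_local_structure(self):
        """Piecewise-constant landscape: small tuned k beats the N/3 default."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 10, size=(60, 1))
            y = np.floor(X[:, 0])  # 10 plateaus
            Xte = rng.uniform(0, 10, size=(60, 1))
            yte = np.floor(Xte[:, 0])
            k = tune_knn(X, y, seed=seed)
            mae_tuned = np.mean(np.abs(
                KNNUncertaintyRegressor(k).fit(X, y).predict(Xte) - yte))
            mae_default = np.mean(np.abs(
                KNNUncertaintyRegressor().fit(X, y).predict(Xte) - yte))
            wins += mae_tuned < mae_default
        assert wins >= 6
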