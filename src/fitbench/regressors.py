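"""Uncertainty-aware regressors: kNN, Random Forest, and exact Gaussian processes.

Every regressor returns a :class:`PredictiveDistribution` (per-point mean ŷᵢ
and variance σ̂ᵢ²) so downstream calibration metrics and acquisition functions
can be computed uniformly.  All estimators follow the scikit-learn estimator
protocol (``fit``/``predict``, ``get_params``/``set_params``, fitted
attributes with a trailing underscore).

The GP is exact: zero-mean prior on standardized labels, Gaussian observation
noise y = f(x) + ε, ε ~ N(0, σ_ε² I), and hyperparameters chosen by
maximizing the log marginal likelihood plus log prior density (MAP) with
σ² ~ Γ⁻¹(3, 3), l ~ Γ⁻¹(3, 3) and σ_ε² uniform on [0.01, 1.0], using
multi-start L-BFGS with analytic gradients.  The reported predictive variance
includes the noise term σ_ε² (the predictive, not latent, distribution).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.spatial.distance import cdist
from scipy.stats import invgamma
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .encodings import as_matrix, fit_standardizer

VARIANCE_FLOOR = 1e-12

KERNELS = ("linear", "squared_exponential", "matern52")

# Inverse-gamma prior shared by signal variance and lengthscale.
_PRIOR_A = 3.0
_PRIOR_B = 3.0
NOISE_BOUNDS = (0.01, 1.0)


@dataclass
class PredictiveDistribution:
    """Per-point predictive mean and variance on the original label scale."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance shape mismatch")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.variance))):
            raise ValueError("non-finite predictive distribution")
        if np.any(self.variance < 0):
            raise ValueError("negative predictive variance")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def __len__(self) -> int:
        return len(self.mean)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _sqdist(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    return cdist(X, Z, "sqeuclidean")


def linear_kernel(X, Z, signal_variance=1.0):
    """k(x, x') = Σ_d σ_d² x_d x'_d; a scalar σ² is shared across dimensions."""
    X, Z = np.atleast_2d(X), np.atleast_2d(Z)
    sv = np.asarray(signal_variance, dtype=float)
    if sv.ndim == 0:
        return sv * (X @ Z.T)
    return (X * sv) @ Z.T


def squared_exponential_kernel(X, Z, signal_variance=1.0, lengthscale=1.0):
    """k(x, x') = σ² exp(−‖x−x'‖² / (2 l²))."""
    return signal_variance * np.exp(-_sqdist(np.atleast_2d(X), np.atleast_2d(Z))
                                    / (2.0 * lengthscale**2))


def matern52_kernel(X, Z, signal_variance=1.0, lengthscale=1.0):
    """k(x, x') = σ² (1 + √5 r/l + 5r²/(3l²)) exp(−√5 r/l), r = ‖x−x'‖."""
    r = np.sqrt(np.maximum(_sqdist(np.atleast_2d(X), np.atleast_2d(Z)), 0.0))
    s = math.sqrt(5.0) * r / lengthscale
    return signal_variance * (1.0 + s + s**2 / 3.0) * np.exp(-s)


def kernel_eval(kind, x, xp, signal_variance=1.0, lengthscale=1.0) -> float:
    """Evaluate a single kernel entry k(x, x')."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    xp = np.atleast_1d(np.asarray(xp, dtype=float))
    if x.shape != xp.shape:
        raise ValueError("kernel inputs must have equal dimension")
    if kind == "linear":
        K = linear_kernel(x[None, :], xp[None, :], signal_variance)
    elif kind == "squared_exponential":
        K = squared_exponential_kernel(x[None, :], xp[None, :], signal_variance, lengthscale)
    elif kind == "matern52":
        K = matern52_kernel(x[None, :], xp[None, :], signal_variance, lengthscale)
    else:
        raise ValueError(f"unknown kernel {kind!r}")
    return float(K[0, 0])


def _gram_base(kind, X):
    """Hyperparameter-independent part of the Gram computation.

    Linear: the raw inner-product matrix; stationary kernels: squared
    distances.  Computed once per fit so each optimizer step is O(n²).
    """
    if kind == "linear":
        return X @ X.T
    return _sqdist(X, X)


def _gram_and_grads(kind, base, signal_variance, lengthscale):
    """Gram matrix and its derivatives w.r.t. log σ² and log l."""
    if kind == "linear":
        K = signal_variance * base
        return K, {"log_sv": K}
    if kind == "squared_exponential":
        K = signal_variance * np.exp(-base / (2.0 * lengthscale**2))
        return K, {"log_sv": K, "log_ls": K * base / lengthscale**2}
    if kind == "matern52":
        r = np.sqrt(np.maximum(base, 0.0))
        s = math.sqrt(5.0) * r / lengthscale
        e = np.exp(-s)
        K = signal_variance * (1.0 + s + s**2 / 3.0) * e
        # dK/ds = −σ² e^{−s} s(1+s)/3; ds/d log l = −s
        dK_dlogls = signal_variance * e * s**2 * (1.0 + s) / 3.0
        return K, {"log_sv": K, "log_ls": dK_dlogls}
    raise ValueError(f"unknown kernel {kind!r}")


def _chol_with_jitter(K: np.ndarray):
    """Cholesky with an escalating jitter ladder 1e-8 → 1e-4."""
    jitter = 0.0
    for j in (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4):
        try:
            L = cholesky(K + j * np.eye(K.shape[0]), lower=True)
            return L, j
        except np.linalg.LinAlgError:
            jitter = j
            continue
    raise np.linalg.LinAlgError(
        f"covariance not positive definite even with jitter {jitter}"
    )


def log_marginal_likelihood(K: np.ndarray, y: np.ndarray, noise_variance: float) -> float:
    """log p(ȳ | X, θ) = −½ȳᵀ(K+σ_ε²I)⁻¹ȳ − ½log|K+σ_ε²I| − (n/2)log 2π."""
    n = len(y)
    Ky = K + noise_variance * np.eye(n)
    L, _ = _chol_with_jitter(Ky)
    alpha = cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2 * math.pi)
    )


def _log_invgamma(x: float) -> tuple[float, float]:
    """log pdf of Γ⁻¹(3, 3) at x and its derivative w.r.t. log x."""
    logp = float(invgamma.logpdf(x, _PRIOR_A, scale=_PRIOR_B))
    dlogp_dlogx = -(_PRIOR_A + 1.0) + _PRIOR_B / x
    return logp, dlogp_dlogx


class ExactGPRegressor(RegressorMixin, BaseEstimator):
    """Exact GP regression with linear / squared-exponential / Matérn-5/2 kernels.

    Parameters
    ----------
    kernel : {"linear", "squared_exponential", "matern52"}
    signal_variance, lengthscale, noise_variance : float
        Initial (or, with ``optimize=False``, fixed) hyperparameters.  The
        lengthscale is ignored by the linear kernel.
    optimize : bool
        Maximize log marginal likelihood + log prior (MAP) over the
        hyperparameters; the noise variance stays inside [0.01, 1.0].
    n_restarts : int
        Number of extra L-BFGS starts drawn from the hyperparameter priors.
    standardize : bool
        Standardize labels on the training data (predictions are returned on
        the original scale either way).
    max_iter : int
        L-BFGS iteration cap per start.
    """

    def __init__(
        self,
        kernel: str = "matern52",
        signal_variance: float = 1.0,
        lengthscale: float = 1.0,
        noise_variance: float = 0.1,
        optimize: bool = True,
        n_restarts: int = 3,
        standardize: bool = True,
        max_iter: int = 500,
        random_state=None,
    ):
        self.kernel = kernel
        self.signal_variance = signal_variance
        self.lengthscale = lengthscale
        self.noise_variance = noise_variance
        self.optimize = optimize
        self.n_restarts = n_restarts
        self.standardize = standardize
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _objective_and_grad(self, z: np.ndarray, base: np.ndarray, y: np.ndarray):
        """Negative (LML + log prior) and gradient in log-parameter space."""
        has_ls = self.kernel != "linear"
        sv = math.exp(z[0])
        ls = math.exp(z[1]) if has_ls else 1.0
        nv = math.exp(z[-1])
        n = len(y)

        K, grads = _gram_and_grads(self.kernel, base, sv, ls)
        Ky = K + nv * np.eye(n)
        L, _ = _chol_with_jitter(Ky)
        alpha = cho_solve((L, True), y)
        lml = -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2 * math.pi)

        Kinv = cho_solve((L, True), np.eye(n))
        A = np.outer(alpha, alpha) - Kinv

        obj = lml
        g = np.zeros_like(z)
        # d lml / d log θ = ½ tr(A dK/d log θ)
        g[0] = 0.5 * np.sum(A * grads["log_sv"])
        lp, dlp = _log_invgamma(sv)
        obj += lp
        g[0] += dlp
        if has_ls:
            g[1] = 0.5 * np.sum(A * grads["log_ls"])
            lp, dlp = _log_invgamma(ls)
            obj += lp
            g[1] += dlp
        # Noise: dK/d log σ_ε² = σ_ε² I; uniform prior contributes a constant.
        g[-1] = 0.5 * nv * np.trace(A)
        return -obj, -g

    def _starts(self, rng) -> list[np.ndarray]:
        has_ls = self.kernel != "linear"
        init = [math.log(self.signal_variance)]
        if has_ls:
            init.append(math.log(self.lengthscale))
        init.append(math.log(np.clip(self.noise_variance, *NOISE_BOUNDS)))
        starts = [np.array(init)]
        for _ in range(self.n_restarts):
            s = [math.log(invgamma.rvs(_PRIOR_A, scale=_PRIOR_B, random_state=rng))]
            if has_ls:
                s.append(math.log(invgamma.rvs(_PRIOR_A, scale=_PRIOR_B, random_state=rng)))
            s.append(math.log(rng.uniform(*NOISE_BOUNDS)))
            starts.append(np.array(s))
        return starts

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = as_matrix(X)
        X, y = check_X_y(X, y)
        if len(y) < 2:
            raise ValueError("GP regression needs at least 2 training points")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")
        rng = check_random_state(self.random_state)

        if self.standardize:
            self.standardizer_ = fit_standardizer(y)
            y_std = self.standardizer_.apply(y)
        else:
            self.standardizer_ = None
            y_std = np.asarray(y, dtype=float)

        has_ls = self.kernel != "linear"
        bounds = [(-20.0, 20.0)]
        if has_ls:
            bounds.append((-20.0, 20.0))
        bounds.append((math.log(NOISE_BOUNDS[0]), math.log(NOISE_BOUNDS[1])))

        base = _gram_base(self.kernel, X)
        if self.optimize:
            best_z, best_obj = None, np.inf
            starts = self._starts(rng)
            self.initial_objective_ = -self._objective_and_grad(starts[0], base, y_std)[0]
            for z0 in starts:
                # The start itself is a candidate even if L-BFGS makes no progress.
                f0 = self._objective_and_grad(z0, base, y_std)[0]
                if f0 < best_obj:
                    best_z, best_obj = z0, f0
                try:
                    res = optimize.minimize(
                        self._objective_and_grad, z0, args=(base, y_std),
                        jac=True, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": self.max_iter},
                    )
                except np.linalg.LinAlgError:
                    continue
                if np.isfinite(res.fun) and res.fun < best_obj:
                    best_z, best_obj = res.x, res.fun
            z = best_z
            self.objective_ = -best_obj
        else:
            z = np.array(
                [math.log(self.signal_variance)]
                + ([math.log(self.lengthscale)] if has_ls else [])
                + [math.log(self.noise_variance)]
            )
            self.objective_ = -self._objective_and_grad(z, base, y_std)[0]
            self.initial_objective_ = self.objective_

        self.signal_variance_ = math.exp(z[0])
        self.lengthscale_ = math.exp(z[1]) if has_ls else None
        self.noise_variance_ = math.exp(z[-1])

        K, _ = _gram_and_grads(self.kernel, base, self.signal_variance_,
                               self.lengthscale_ or 1.0)
        Ky = K + self.noise_variance_ * np.eye(len(y_std))
        self.L_, self.jitter_ = _chol_with_jitter(Ky)
        self.alpha_ = cho_solve((self.L_, True), y_std)
        self.log_marginal_likelihood_ = float(
            -0.5 * y_std @ self.alpha_
            - np.sum(np.log(np.diag(self.L_)))
            - 0.5 * len(y_std) * math.log(2 * math.pi)
        )
        self.X_train_ = X
        self.y_train_std_ = y_std
        self.n_features_in_ = X.shape[1]
        return self

    def _kernel_cross(self, A, B):
        if self.kernel == "linear":
            return linear_kernel(A, B, self.signal_variance_)
        if self.kernel == "squared_exponential":
            return squared_exponential_kernel(A, B, self.signal_variance_, self.lengthscale_)
        return matern52_kernel(A, B, self.signal_variance_, self.lengthscale_)

    def predict_dist(self, X) -> PredictiveDistribution:
        """Posterior predictive mean and variance (noise included) per point."""
        check_is_fitted(self, "alpha_")
        X = check_array(as_matrix(X))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: model trained on d={self.n_features_in_}, "
                f"got d={X.shape[1]}"
            )
        Ks = self._kernel_cross(X, self.X_train_)           # n* × n
        mean_std = Ks @ self.alpha_
        V = cho_solve((self.L_, True), Ks.T)                 # n × n*
        if self.kernel == "linear":
            kss = self.signal_variance_ * np.einsum("ij,ij->i", X, X)
        else:
            kss = np.full(X.shape[0], self.signal_variance_)
        var_std = kss - np.einsum("ij,ji->i", Ks, V) + self.noise_variance_
        var_std = np.maximum(var_std, VARIANCE_FLOOR)
        if self.standardizer_ is not None:
            mean = self.standardizer_.invert(mean_std)
            var = self.standardizer_.invert_variance(var_std)
        else:
            mean, var = mean_std, var_std
        return PredictiveDistribution(mean=mean, variance=var)

    def predict(self, X, return_std: bool = False):
        dist = self.predict_dist(X)
        if return_std:
            return dist.mean, dist.sd
        return dist.mean

    def save(self, path) -> None:
        """Serialize the fitted model to a .npz container.

        Stores the kernel kind, the fitted hyperparameters θ, the training
        representation and standardized labels, and the label standardizer;
        the Cholesky factorization is recomputed on load.
        """
        check_is_fitted(self, "alpha_")
        meta = {
            "kernel": self.kernel,
            "signal_variance": self.signal_variance_,
            "lengthscale": self.lengthscale_,
            "noise_variance": self.noise_variance_,
            "standardizer_mu": None if self.standardizer_ is None else self.standardizer_.mu,
            "standardizer_sd": None if self.standardizer_ is None else self.standardizer_.sd,
        }
        import json

        np.savez(path, X_train=self.X_train_, y_train_std=self.y_train_std_,
                 meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "ExactGPRegressor":
        import json

        from .encodings import LabelStandardizer

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(kernel=meta["kernel"],
                    signal_variance=meta["signal_variance"],
                    lengthscale=meta["lengthscale"] or 1.0,
                    noise_variance=meta["noise_variance"],
                    optimize=False, standardize=False)
        model.fit(data["X_train"], data["y_train_std"])
        if meta["standardizer_mu"] is not None:
            model.standardizer_ = LabelStandardizer(meta["standardizer_mu"],
                                                    meta["standardizer_sd"])
        return model


class KNNUncertaintyRegressor(RegressorMixin, BaseEstimator):
    """k-nearest-neighbour regression with neighbour-label variance.

    Prediction is the mean of the k nearest training labels (Euclidean
    distance in representation space); the predictive variance is the
    empirical variance of those labels, floored at 1e-12.  Distance ties are
    broken by lowest training index.  ``n_neighbors=None`` uses the
    unoptimized default k = ⌈N/3⌉, or the budgeted internal-CV search when
    ``tune=True``.
    """

    def __init__(self, n_neighbors: int | None = None, tune: bool = False,
                 random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.tune = tune
        self.random_state = random_state

    def fit(self, X, y):
        X = as_matrix(X)
        X, y = check_X_y(X, y)
        if self.n_neighbors is not None:
            k = self.n_neighbors
        elif self.tune:
            k = tune_knn(X, y, seed=self.random_state)
        else:
            k = math.ceil(len(y) / 3)
        if not 1 <= k <= len(y):
            raise ValueError(f"k={k} outside [1, {len(y)}]")
        self.k_ = int(k)
        self.X_train_ = X
        self.y_train_ = np.asarray(y, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_dist(self, X) -> PredictiveDistribution:
        check_is_fitted(self, "X_train_")
        X = check_array(as_matrix(X))
        D = cdist(X, self.X_train_)
        # Stable sort: equal distances resolve to the lowest training index.
        nn = np.argsort(D, axis=1, kind="stable")[:, : self.k_]
        neigh = self.y_train_[nn]
        mean = neigh.mean(axis=1)
        var = np.maximum(neigh.var(axis=1), VARIANCE_FLOOR)
        return PredictiveDistribution(mean=mean, variance=var)

    def predict(self, X, return_std: bool = False):
        dist = self.predict_dist(X)
        return (dist.mean, dist.sd) if return_std else dist.mean


def ensemble_mean_variance(tree_predictions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Across-ensemble mean and variance: σ̂² = mean(ŷ_tree²) − mean(ŷ_tree)²."""
    P = np.asarray(tree_predictions, dtype=float)  # n_trees × n_points
    mean = P.mean(axis=0)
    var = np.maximum((P**2).mean(axis=0) - mean**2, 0.0)
    return mean, var


class RandomForestUncertaintyRegressor(RegressorMixin, BaseEstimator):
    """Random-forest regression with an across-tree predictive variance.

    With ``tune=True`` the ensemble size is chosen by the budgeted internal-CV
    search instead of ``n_estimators``.
    """

    def __init__(self, n_estimators: int = 100, tune: bool = False, random_state=None):
        self.n_estimators = n_estimators
        self.tune = tune
        self.random_state = random_state

    def fit(self, X, y):
        X = as_matrix(X)
        X, y = check_X_y(X, y)
        n_estimators = self.n_estimators
        if self.tune:
            n_estimators = tune_rf(X, y, seed=self.random_state or 0)
        if n_estimators < 2:
            raise ValueError("ensemble variance needs n_estimators >= 2")
        self.forest_ = RandomForestRegressor(
            n_estimators=n_estimators, random_state=self.random_state
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_dist(self, X) -> PredictiveDistribution:
        check_is_fitted(self, "forest_")
        X = check_array(as_matrix(X))
        per_tree = np.stack([t.predict(X) for t in self.forest_.estimators_])
        mean, var = ensemble_mean_variance(per_tree)
        return PredictiveDistribution(mean=mean, variance=np.maximum(var, VARIANCE_FLOOR))

    def predict(self, X, return_std: bool = False):
        dist = self.predict_dist(X)
        return (dist.mean, dist.sd) if return_std else dist.mean


# ---------------------------------------------------------------------------
# Convenience functional wrappers
# ---------------------------------------------------------------------------

def knn_fit_predict(X, y, X_star, k: int) -> PredictiveDistribution:
    return KNNUncertaintyRegressor(n_neighbors=k).fit(X, y).predict_dist(X_star)


def rf_fit_predict(X, y, X_star, n_estimators: int, seed=None) -> PredictiveDistribution:
    return (
        RandomForestUncertaintyRegressor(n_estimators=n_estimators, random_state=seed)
        .fit(X, y)
        .predict_dist(X_star)
    )


def gp_fit(X, y, kernel: str = "matern52", seed=None, **kwargs) -> ExactGPRegressor:
    return ExactGPRegressor(kernel=kernel, random_state=seed, **kwargs).fit(X, y)


def gp_predict(model: ExactGPRegressor, X_star) -> PredictiveDistribution:
    return model.predict_dist(X_star)


# ---------------------------------------------------------------------------
# Hyperparameter tuning (internal 3-fold CV on mean absolute error)
# ---------------------------------------------------------------------------

def _internal_cv_mae(make_estimator, X, y, seed) -> float:
    X = as_matrix(X)
    y = np.asarray(y, dtype=float)
    kf = KFold(n_splits=3, shuffle=True, random_state=seed)
    errs = []
    for tr, te in kf.split(X):
        est = make_estimator()
        est.fit(X[tr], y[tr])
        errs.append(np.mean(np.abs(est.predict(X[te]) - y[te])))
    return float(np.mean(errs))


def _discrete_ei_minimize(f, candidates: np.ndarray, budget: int, rng) -> int:
    """Budget-limited minimization over an integer grid.

    Exhaustive when the grid fits the budget; otherwise EI with a
    random-forest surrogate (tree-ensemble variance) over the grid.
    """
    candidates = np.asarray(candidates)
    if len(candidates) <= budget:
        scores = [f(int(c)) for c in candidates]
        return int(candidates[int(np.argmin(scores))])

    n_init = min(10, budget)
    tried = list(rng.choice(len(candidates), size=n_init, replace=False))
    scores = {i: f(int(candidates[i])) for i in tried}
    from .bayes_opt import expected_improvement

    while len(scores) < budget:
        xs = np.array(sorted(scores)).reshape(-1, 1).astype(float)
        ys = np.array([scores[int(i)] for i in sorted(scores)])
        surrogate = RandomForestRegressor(
            n_estimators=50, random_state=check_random_state(rng.integers(2**31))
        ).fit(xs, ys)
        remaining = np.array([i for i in range(len(candidates)) if i not in scores])
        per_tree = np.stack(
            [t.predict(candidates[remaining].reshape(-1, 1).astype(float))
             for t in surrogate.estimators_]
        )
        mu, var = ensemble_mean_variance(per_tree)
        best = min(scores.values())
        # Minimization: EI of the *negated* objective.
        ei = expected_improvement(-mu, np.sqrt(var), -best)
        nxt = int(remaining[int(np.argmax(ei))])
        scores[nxt] = f(int(candidates[nxt]))
    best_i = min(scores, key=lambda i: scores[i])
    return int(candidates[best_i])


def tune_knn(X, y, seed: int = 0, budget: int = 75) -> int:
    """Tuned neighbour count k ∈ [1, ⌊0.95·N/3⌋] by internal 3-fold CV MAE."""
    N = len(np.asarray(y))
    if N < 6:
        warnings.warn("too few samples for internal 3-fold CV; "
                      "falling back to default k = ceil(N/3)")
        return max(1, math.ceil(N / 3))
    k_max = max(1, math.floor(0.95 * N / 3))
    rng = np.random.default_rng(seed)

    def score(k: int) -> float:
        return _internal_cv_mae(lambda: KNNUncertaintyRegressor(n_neighbors=k), X, y, seed)

    return _discrete_ei_minimize(score, np.arange(1, k_max + 1), budget, rng)


def tune_rf(X, y, seed: int = 0, budget: int = 15) -> int:
    """Tuned n_estimators ∈ [2, N] by internal 3-fold CV MAE."""
    N = len(np.asarray(y))
    if N < 6:
        warnings.warn("too few samples for internal 3-fold CV; "
                      "falling back to the 100-tree default")
        return 100
    rng = np.random.default_rng(seed)

    def score(n_est: int) -> float:
        return _internal_cv_mae(
            lambda: RandomForestUncertaintyRegressor(n_estimators=n_est, random_state=seed),
            X, y, seed,
        )

    return _discrete_ei_minimize(score, np.arange(2, N + 1), budget, rng)
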