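"""Accuracy and uncertainty-quality metrics.

Accuracy: adjusted R² (improvement over the training-mean baseline), MSE, and
Spearman rank correlation.  Uncertainty quality: reduced χ² (≈1 when
calibrated, >1 overconfident, <1 underconfident), calibration curves built
from the probability integral transform of normalized residuals, expected
calibration error (ECE), sharpness (coefficient of variation of the
predictive variances), and confidence curves (loss over the
lowest-uncertainty subsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def _check_equal(*arrays):
    arrs = [np.asarray(a, dtype=float) for a in arrays]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("input vectors must have equal length")
    return arrs


def adjusted_r2(y_test, y_hat, mu_train: float) -> float:
    """R² = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−μ_train)², with the *training* mean baseline."""
    y, yh = _check_equal(y_test, y_hat)
    if y.size < 1:
        raise ValueError("empty input")
    denom = np.sum((y - mu_train) ** 2)
    if denom == 0:
        raise ValueError("all test labels equal the training mean; R² undefined")
    return float(1.0 - np.sum((y - yh) ** 2) / denom)


def mse(y, y_hat) -> float:
    """Mean squared residuals."""
    y, yh = _check_equal(y, y_hat)
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - yh) ** 2))


def spearman_rho(y, y_hat) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    y, yh = _check_equal(y, y_hat)
    if y.size < 2:
        raise ValueError("need >= 2 observations")
    if np.ptp(y) == 0 or np.ptp(yh) == 0:
        raise ValueError("constant input vector: rank correlation undefined")
    rho = stats.spearmanr(y, yh).statistic
    return float(rho)


def reduced_chi2(y, y_hat, sigma_hat) -> float:
    """χ² = (1/(N−1)) Σ ((yᵢ−ŷᵢ)/σ̂ᵢ)²."""
    y, yh, s = _check_equal(y, y_hat, sigma_hat)
    if y.size < 2:
        raise ValueError("need >= 2 observations")
    if np.any(s <= 0):
        raise ValueError("predictive standard deviations must be positive")
    z = (y - yh) / s
    return float(np.sum(z**2) / (y.size - 1))


def calibration_curve(y, y_hat, sigma_hat, q: int = 10):
    """Empirical coverage of probability-integral-transformed residuals.

    At each level p_j = j/q the empirical coverage is the fraction of points
    with Φ((yᵢ−ŷᵢ)/σ̂ᵢ) ≤ p_j; perfectly calibrated Gaussian predictions give
    coverage ≈ level.
    """
    y, yh, s = _check_equal(y, y_hat, sigma_hat)
    if y.size < q:
        raise ValueError("need n >= q observations")
    if np.any(s <= 0):
        raise ValueError("predictive standard deviations must be positive")
    pit = stats.norm.cdf((y - yh) / s)
    levels = np.arange(1, q + 1) / q
    coverage = np.array([np.mean(pit <= p) for p in levels])
    return levels, coverage


def ece(levels, empirical_coverage) -> float:
    """Expected calibration error: mean |coverage − level|."""
    lv, cov = _check_equal(levels, empirical_coverage)
    return float(np.mean(np.abs(cov - lv)))


def sharpness(sigma_hat_sq) -> float:
    """Coefficient of variation of the predictive variances (sample sd)."""
    v = np.asarray(sigma_hat_sq, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 variances")
    m = np.mean(v)
    if m <= 0:
        raise ValueError("mean predictive variance must be positive")
    return float(np.std(v, ddof=1) / m)


def confidence_curve(y, y_hat, sigma_hat, q: int = 10, literal: bool = False):
    """Squared-error loss over retained sets of increasing uncertainty.

    Thresholds h_j are the j/q-quantiles of σ̂; entry j is the mean squared
    error over {i : σ̂ᵢ ≤ h_j} (or, with ``literal=True``, the sum of retained
    squared errors divided by the total N).  NaN marks an empty retained set.
    """
    y, yh, s = _check_equal(y, y_hat, sigma_hat)
    if y.size < q:
        raise ValueError("need n >= q observations")
    sq = (y - yh) ** 2
    out = np.empty(q)
    for j in range(1, q + 1):
        h = np.quantile(s, j / q)
        keep = s <= h
        if not keep.any():
            out[j - 1] = np.nan
        elif literal:
            out[j - 1] = np.sum(sq[keep]) / y.size
        else:
            out[j - 1] = np.mean(sq[keep])
    return out


@dataclass
class CalibrationReport:
    """Bundle of uncertainty-quality diagnostics at q quantile levels."""

    q: int
    levels: np.ndarray
    empirical_coverage: np.ndarray
    ece: float
    sharpness: float
    chi2: float
    confidence_curve: np.ndarray


def calibration_report(y, y_hat, sigma_hat, q: int = 10) -> CalibrationReport:
    levels, coverage = calibration_curve(y, y_hat, sigma_hat, q)
    s = np.asarray(sigma_hat, dtype=float)
    return CalibrationReport(
        q=q,
        levels=levels,
        empirical_coverage=coverage,
        ece=ece(levels, coverage),
        sharpness=sharpness(s**2),
        chi2=reduced_chi2(y, y_hat, sigma_hat),
        confidence_curve=confidence_curve(y, y_hat, sigma_hat, q),
    )
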