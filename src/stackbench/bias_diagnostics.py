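"""Bias diagnostics and reference bias-correction baselines for regression
predictors.

Random-forest regressors tend to under-predict high responses and
over-predict low ones, so a scatter of residuals (observed - predicted)
against the observed values shows a linear trend instead of a flat cloud.
The angle theta that the fitted residual-on-observed line makes with the
horizontal axis measures this bias: theta = 0 for an unbiased predictor,
and theta approaches 45 degrees for a constant (mean) predictor.

The eigen diagnostic examines the covariance of the residuals of several
component models: when the dominant normalized eigenvalue explains more
than 90% of the variation, the residuals share one axis of variation and a
linear stack can remove the common bias efficiently.

Two reference corrections are provided for comparison with stacking:

* BC1 fits a second forest mapping validation covariates to validation
  residuals and adds the predicted residuals to the base predictions;
* RRot rotates the residual-vs-predicted trend line to horizontal about the
  centroid of the validation (predicted, residual) points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import LabeledDataset
from .predictors import ForestConfig, ForestModel, fit_forest

__all__ = [
    "BiasReport",
    "EigenReport",
    "RRotMap",
    "bias_angle",
    "bootstrap_theta_ci",
    "residual_eigens",
    "bc1_correct",
    "fit_rrot",
    "rrot_correct",
]


@dataclass(frozen=True)
class BiasReport:
    """Bias angle in degrees, optional 95% bootstrap bounds, and the
    underlying residual-on-observed OLS fit."""

    theta_deg: float
    slope: float
    intercept: float
    n: int
    theta_lo: float | None = None
    theta_hi: float | None = None


@dataclass(frozen=True)
class EigenReport:
    """Normalized residual-covariance eigen-spectrum (descending, sums to 1)
    and the variance-condition flag (dominant fraction > 0.9)."""

    normalized_eigenvalues: np.ndarray
    dominant_fraction: float
    condition_met: bool
    degenerate: bool = False


def _check_pair(observed: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if observed.shape[0] < 3:
        raise ValueError("need at least 3 points to estimate a bias angle")
    if np.ptp(observed) == 0:
        raise ValueError("observed values are constant; bias regression undefined")
    return observed, predicted


def _theta_from_pair(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """OLS of residuals on observed; returns (slope, intercept, theta_deg)."""
    residuals = observed - predicted
    slope, intercept, *_ = stats.linregress(observed, residuals)
    return float(slope), float(intercept), float(np.degrees(np.arctan(slope)))


def bias_angle(observed: np.ndarray, predicted: np.ndarray) -> BiasReport:
    """Bias angle of a predictor from observed/predicted pairs.

    Residuals r = observed - predicted are regressed on the observed values;
    theta is arctan of the OLS slope, in degrees.  A perfect predictor gives
    theta = 0; predicting the mean of the observed values for every point
    gives slope 1, hence theta = 45 degrees.
    """
    observed, predicted = _check_pair(observed, predicted)
    slope, intercept, theta = _theta_from_pair(observed, predicted)
    return BiasReport(theta_deg=theta, slope=slope, intercept=intercept, n=observed.shape[0])


def bootstrap_theta_ci(
    observed: np.ndarray,
    predicted: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> BiasReport:
    """Bias angle with a percentile bootstrap 95% confidence interval.

    Pairs (observed, predicted) are resampled jointly ``n_boot`` times; the
    2.5th and 97.5th percentiles of the resampled angles form the bounds.
    Degenerate resamples (constant observed values) are redrawn implicitly
    by being skipped.
    """
    observed, predicted = _check_pair(observed, predicted)
    slope, intercept, theta = _theta_from_pair(observed, predicted)
    rng = np.random.default_rng(seed)
    n = observed.shape[0]
    thetas = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.ptp(observed[idx]) == 0:
            continue
        thetas[filled] = _theta_from_pair(observed[idx], predicted[idx])[2]
        filled += 1
    lo, hi = np.percentile(thetas, [2.5, 97.5])
    return BiasReport(
        theta_deg=theta,
        slope=slope,
        intercept=intercept,
        n=n,
        theta_lo=float(lo),
        theta_hi=float(hi),
    )


def residual_eigens(residual_matrix: np.ndarray, threshold: float = 0.9) -> EigenReport:
    """Eigen-spectrum of the covariance of component-model residuals.

    Columns are the residuals of the individual models; the covariance of
    the column-centered matrix is eigen-decomposed, and the eigenvalues are
    normalized to sum to one and sorted descending.  ``condition_met`` is
    true when the dominant eigenvalue explains more than ``threshold``
    (default 90%) of the variation — the regime in which linear stacking
    corrects bias efficiently.
    """
    R = np.asarray(residual_matrix, dtype=float)
    if R.ndim != 2:
        raise ValueError("residual_matrix must be 2-D (n x n_models)")
    n, n_m = R.shape
    if n_m < 2:
        raise ValueError("need at least two component models")
    if n <= n_m:
        raise ValueError("need more observations than models")
    centered = R - R.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (n - 1)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    total = eigvals.sum()
    if total == 0.0:
        return EigenReport(
            normalized_eigenvalues=np.zeros(n_m),
            dominant_fraction=0.0,
            condition_met=False,
            degenerate=True,
        )
    norm = eigvals / total
    return EigenReport(
        normalized_eigenvalues=norm,
        dominant_fraction=float(norm[0]),
        condition_met=bool(norm[0] > threshold),
    )


def bc1_correct(
    base_model: ForestModel,
    validation: LabeledDataset,
    test_X: np.ndarray,
    forest_config: ForestConfig,
) -> np.ndarray:
    """BC1 residual-forest correction.

    A second forest is fitted with the validation covariates as features and
    the validation residuals (y_val - base predictions) as response; the
    corrected test prediction is the base prediction plus the residual
    forest's prediction.  The validation set must be disjoint from the base
    model's training data.
    """
    base_val = base_model.predict(validation.X)
    residuals = validation.Y - base_val
    residual_ds = LabeledDataset(
        sample_ids=validation.sample_ids,
        X=validation.X,
        Y=residuals,
        feature_ids=validation.feature_ids,
    )
    residual_model = fit_forest(residual_ds, forest_config)
    test_X = np.asarray(test_X, dtype=float)
    return base_model.predict(test_X) + residual_model.predict(test_X)


@dataclass(frozen=True)
class RRotMap:
    """The residual-rotation correction map fitted on validation data.

    The residual-vs-predicted OLS line on validation has slope ``slope``;
    rotating it to horizontal about the centroid of the (predicted,
    residual) points adds ``slope * (p - center)`` to a prediction ``p``.
    """

    slope: float
    center: float

    def apply(self, predictions: np.ndarray) -> np.ndarray:
        p = np.asarray(predictions, dtype=float)
        return p + self.slope * (p - self.center)


def fit_rrot(base_preds_val: np.ndarray, y_val: np.ndarray) -> RRotMap:
    """Fit the rotation map from validation predictions and responses.

    If the validation predictions are constant the trend is inestimable and
    the identity map is returned with a warning.
    """
    p = np.asarray(base_preds_val, dtype=float)
    y = np.asarray(y_val, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("base_preds_val and y_val must be 1-D and aligned")
    if np.ptp(p) == 0:
        warnings.warn(
            "constant validation predictions; residual rotation is the identity",
            RuntimeWarning,
            stacklevel=2,
        )
        return RRotMap(slope=0.0, center=float(p.mean()) if p.size else 0.0)
    residuals = y - p
    slope, _, *_ = stats.linregress(p, residuals)
    return RRotMap(slope=float(slope), center=float(p.mean()))


def rrot_correct(
    base_preds_val: np.ndarray,
    y_val: np.ndarray,
    base_preds_test: np.ndarray,
) -> np.ndarray:
    """RRot correction: derive the rotation on validation, apply to test.

    Post-condition: after applying the map to the validation predictions,
    the OLS slope of (y - p') on p' is zero — the residual trend line has
    been rotated flat.  Applying the correction twice equals applying it
    once (the re-fitted slope is zero).
    """
    rot = fit_rrot(base_preds_val, y_val)
    return rot.apply(np.asarray(base_preds_test, dtype=float))
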