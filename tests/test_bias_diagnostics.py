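"""Bias angle, bootstrap CIs, residual eigen-spectrum, BC1 and RRot."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stackbench.bias_diagnostics import (
    bc1_correct,
    bias_angle,
    bootstrap_theta_ci,
    fit_rrot,
    residual_eigens,
    rrot_correct,
)
from stackbench.datasets import LabeledDataset
from stackbench.predictors import ForestConfig, fit_forest


def _val_slope(preds, y):
    """OLS slope of residuals on predictions (independent recomputation)."""
    r = y - preds
    p = preds - preds.mean()
    return float(p @ (r - r.mean()) / (p @ p))


class TestBiasAngle:
    def test_perfect_predictor_has_zero_angle(self, rng):
        y = rng.standard_normal(50)
        assert bias_angle(y, y).theta_deg == pytest.approx(0.0)

    def test_mean_predictor_has_45_degree_angle(self, rng):
        y = rng.standard_normal(50)
        pred = np.full(50, y.mean())
        # slope of (y - ybar) on y is exactly 1
        assert bias_angle(y, pred).theta_deg == pytest.approx(45.0)

    def test_matches_ols_oracle(self, rng):
        y = rng.standard_normal(80)
        pred = 0.6 * y + rng.standard_normal(80) * 0.2
        report = bias_angle(y, pred)
        slope = _val_slope(np.zeros_like(y) + pred, y)
        # independent slope computed from covariance of residual on observed
        r = y - pred
        yc = y - y.mean()
        expected_slope = yc @ (r - r.mean()) / (yc @ yc)
        assert report.slope == pytest.approx(expected_slope)
        assert report.theta_deg == pytest.approx(np.degrees(np.arctan(expected_slope)))

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bias_angle(np.ones(10), np.zeros(10))

    @given(st.floats(-5, 5))
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(40)
        pred = 0.5 * y
        a = bias_angle(y, pred).theta_deg
        b = bias_angle(y + c, pred + c).theta_deg
        assert a == pytest.approx(b, abs=1e-8)


class TestBootstrapThetaCI:
    def test_zero_residuals_give_degenerate_ci(self, rng):
        y = rng.standard_normal(30)
        report = bootstrap_theta_ci(y, y, n_boot=200, seed=0)
        assert report.theta_lo == pytest.approx(0.0)
        assert report.theta_hi == pytest.approx(0.0)

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (50, 500):
            rng = np.random.default_rng(7)
            y = rng.standard_normal(n)
            pred = 0.7 * y + 0.3 * rng.standard_normal(n)
            r = bootstrap_theta_ci(y, pred, n_boot=400, seed=1)
            widths[n] = r.theta_hi - r.theta_lo
        assert widths[500] < widths[50]

    def test_point_estimate_inside_own_ci(self):
        inside = 0
        n_cases = 100
        for case in range(n_cases):
            rng = np.random.default_rng(1000 + case)
            y = rng.standard_normal(60)
            pred = 0.8 * y + 0.3 * rng.standard_normal(60)
            r = bootstrap_theta_ci(y, pred, n_boot=300, seed=case)
            if r.theta_lo <= r.theta_deg <= r.theta_hi:
                inside += 1
        assert inside >= 0.9 * n_cases


class TestResidualEigens:
    def test_rank_one_residuals(self, rng):
        col = rng.standard_normal(50)
        report = residual_eigens(np.column_stack([col, col]))
        np.testing.assert_allclose(report.normalized_eigenvalues, [1.0, 0.0], atol=1e-12)
        assert report.condition_met

    def test_isotropic_residuals(self):
        # two orthogonal centered columns of equal norm
        a = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        b = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        report = residual_eigens(np.column_stack([a, b]))
        np.testing.assert_allclose(report.normalized_eigenvalues, [0.5, 0.5], atol=1e-12)
        assert not report.condition_met

    def test_matches_explicit_covariance_oracle(self, rng):
        R = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.8], [0.0, 0.4]])
        report = residual_eigens(R)
        C = np.cov(R - R.mean(axis=0), rowvar=False)
        expected = np.sort(np.linalg.eigvals(C).real)[::-1]
        expected /= expected.sum()
        np.testing.assert_allclose(report.normalized_eigenvalues, expected, atol=1e-10)

    def test_zero_variance_degenerate(self):
        report = residual_eigens(np.zeros((10, 3)))
        assert report.degenerate
        assert not report.condition_met

    @given(st.integers(0, 10_000))
    def test_normalized_eigenvalues_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.standard_normal((20, 3))
        norm = residual_eigens(R).normalized_eigenvalues
        assert norm.sum() == pytest.approx(1.0, abs=1e-12)
        assert (norm >= 0).all()
        assert (np.diff(norm) <= 1e-12).all()


def _fitted_base(rng, n_train=60, m=6):
    X = rng.standard_normal((n_train, m))
    y = X @ rng.uniform(0.5, 1.5, m)
    ds = LabeledDataset(
        tuple(f"s{i}" for i in range(n_train)), X, y, tuple(f"f{j}" for j in range(m))
    )
    return fit_forest(ds, ForestConfig(n_trees=10, seed=2)), m


class TestBC1:
    def test_zero_validation_residuals_leave_base_unchanged(self, rng):
        base, m = _fitted_base(rng)
        val_X = rng.standard_normal((20, m))
        val_y = base.predict(val_X)  # residuals identically zero
        val = LabeledDataset(
            tuple(f"v{i}" for i in range(20)), val_X, val_y, base.feature_ids
        )
        test_X = rng.standard_normal((15, m))
        corrected = bc1_correct(base, val, test_X, ForestConfig(n_trees=5, seed=3))
        np.testing.assert_allclose(corrected, base.predict(test_X))

    def test_constant_residual_with_stump_adds_constant(self, rng):
        base, m = _fitted_base(rng)
        val_X = rng.standard_normal((20, m))
        val_y = base.predict(val_X) + 0.37  # constant residual c
        val = LabeledDataset(
            tuple(f"v{i}" for i in range(20)), val_X, val_y, base.feature_ids
        )
        test_X = rng.standard_normal((15, m))
        stump = ForestConfig(n_trees=1, min_node_size=21, seed=5)
        corrected = bc1_correct(base, val, test_X, stump)
        np.testing.assert_allclose(corrected, base.predict(test_X) + 0.37)

    def test_equals_manual_two_model_composition(self, rng):
        base, m = _fitted_base(rng)
        val_X = rng.standard_normal((25, m))
        val_y = rng.standard_normal(25)
        val = LabeledDataset(
            tuple(f"v{i}" for i in range(25)), val_X, val_y, base.feature_ids
        )
        test_X = rng.standard_normal((10, m))
        cfg = ForestConfig(n_trees=8, seed=11)
        corrected = bc1_correct(base, val, test_X, cfg)
        # recompose by hand: second forest on (val_X, residuals)
        resid_ds = LabeledDataset(
            val.sample_ids, val_X, val_y - base.predict(val_X), base.feature_ids
        )
        second = fit_forest(resid_ds, cfg)
        np.testing.assert_allclose(
            corrected, base.predict(test_X) + second.predict(test_X)
        )


class TestRRot:
    def test_flat_trend_leaves_test_unchanged(self, rng):
        preds = rng.standard_normal(50)
        y = preds + rng.standard_normal(50) * 0.1
        rot = fit_rrot(preds, y)
        # force a flat trend by removing it first
        flat_preds = rot.apply(preds)
        test = rng.standard_normal(20)
        corrected = rrot_correct(flat_preds, y, test)
        np.testing.assert_allclose(corrected, test, atol=1e-10)

    def test_post_correction_validation_slope_zero(self, rng):
        y = rng.standard_normal(80)
        preds = 0.5 * y + 0.2 * rng.standard_normal(80)
        corrected_val = rrot_correct(preds, y, preds)
        assert abs(_val_slope(corrected_val, y)) < 1e-8

    def test_idempotent(self, rng):
        y = rng.standard_normal(60)
        preds = 0.6 * y + 0.1 * rng.standard_normal(60)
        test = rng.standard_normal(30)
        once = rrot_correct(preds, y, test)
        val_once = rrot_correct(preds, y, preds)
        twice = rrot_correct(val_once, y, once)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_agrees_with_rotation_about_centroid_oracle(self, rng):
        """The correction equals the vertical gap between the fitted
        residual-trend line and its horizontal rotation about the centroid."""
        y = rng.standard_normal(70)
        preds = 0.4 * y + 0.3 * rng.standard_normal(70)
        rot = fit_rrot(preds, y)
        s = _val_slope(preds, y)
        p_bar = preds.mean()
        r_bar = (y - preds).mean()
        query = rng.standard_normal(12)
        # original line at q: r_bar + s (q - p_bar); rotated (horizontal): r_bar
        gap = (r_bar + s * (query - p_bar)) - r_bar
        np.testing.assert_allclose(rot.apply(query), query + gap, atol=1e-10)

    def test_constant_predictions_identity_with_warning(self, rng):
        y = rng.standard_normal(20)
        preds = np.full(20, 0.3)
        with pytest.warns(RuntimeWarning, match="constant validation"):
            corrected = rrot_correct(preds, y, np.array([0.3, 0.4]))
        np.testing.assert_allclose(corrected, [0.3, 0.4])
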