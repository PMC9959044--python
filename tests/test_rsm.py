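"""Quadratic response-surface fitting and the DoE diagnostic suite."""

import numpy as np
import pytest

from beadopt import datasets
from beadopt.doe import build_ccd
from beadopt.rsm import (
    compute_diagnostics,
    fit_quadratic_rsm,
    model_matrix,
    predict_response,
    press_by_loo,
    term_names,
)
from beadopt.synthetic import gen_ccd_responses


class TestCoefficientRecovery:
    """The study's three printed polynomials, refitted from the raw design."""

    @pytest.mark.parametrize("response", datasets.RESPONSE_NAMES)
    def test_all_thirty_reported_coefficients(self, models, response):
        fitted = models[response].coefficients
        for term, expected in datasets.REFERENCE_COEFFICIENTS[response].items():
            assert fitted[term] == pytest.approx(expected, abs=1e-3), (
                f"{response} {term}"
            )

    def test_spot_pinned_y1_terms(self, models):
        c = models["y1_ee_pct"].coefficients
        assert c["b0"] == pytest.approx(90.0032, abs=1e-3)
        assert c["b1"] == pytest.approx(11.3928, abs=1e-3)

    def test_intercept_equals_center_point_mean(self, design, models):
        # coded-unit fit: b0 is the center-point mean prediction
        centers = np.all(design.coded == 0, axis=1)
        y_center = design.response("y1_ee_pct")[centers]
        assert models["y1_ee_pct"].coefficients["b0"] == pytest.approx(
            y_center.mean(), abs=0.1
        )

    def test_constant_response(self, design):
        d = design.with_responses({"const": np.full(17, 42.0)})
        m = fit_quadratic_rsm(d, "const")
        beta = m.beta
        assert beta[0] == pytest.approx(42.0, abs=1e-9)
        assert np.allclose(beta[1:], 0.0, atol=1e-9)

    def test_noiseless_synthetic_exact_recovery(self):
        d = build_ccd(datasets.FACTORS, n_center=3)
        d = gen_ccd_responses(
            d, datasets.REFERENCE_COEFFICIENTS, cv_pct=0.0, seed=1
        )
        m = fit_quadratic_rsm(d, "y1_ee_pct")
        truth = datasets.REFERENCE_COEFFICIENTS["y1_ee_pct"]
        for term in term_names(3):
            assert m.coefficients[term] == pytest.approx(truth[term], abs=1e-9)
        assert float(m.residuals @ m.residuals) < 1e-16

    def test_rank_deficiency_raises(self, design):
        bad = design.with_responses({"y": np.arange(17.0)})
        bad.coded = np.zeros_like(bad.coded)  # all runs collapse to center
        with pytest.raises(ValueError, match="rank"):
            fit_quadratic_rsm(bad, "y")

    def test_missing_response_raises(self, design):
        with pytest.raises(KeyError):
            fit_quadratic_rsm(design, "nonexistent")


class TestFitInvariants:
    def test_residuals_sum_to_zero_and_leverages(self, models):
        for m in models.values():
            assert m.residuals.sum() == pytest.approx(0, abs=1e-8)
            assert m.hat_diagonal.sum() == pytest.approx(m.n_params, abs=1e-8)
            assert np.allclose(m.fitted + m.residuals, m.observed, atol=1e-10)


class TestPredict:
    def test_center_prediction_is_intercept(self, models):
        for m in models.values():
            assert predict_response(m, [0, 0, 0]) == pytest.approx(
                m.coefficients["b0"]
            )

    def test_reported_optimum_predictions(self, models, optimum_coded):
        # predicted triple at the optimized formulation; the third value
        # is compared at the 1-decimal precision it was reported with
        assert predict_response(
            models["y1_ee_pct"], optimum_coded
        ) == pytest.approx(95.95, abs=0.01)
        assert predict_response(
            models["y2_buoyancy_h"], optimum_coded
        ) == pytest.approx(10.89, abs=0.01)
        assert predict_response(
            models["y3_q6h_pct"], optimum_coded
        ) == pytest.approx(66.0, abs=0.05)

    def test_against_term_by_term_evaluation(self, models):
        # oracle: explicit polynomial evaluation, term by term
        rng = np.random.default_rng(7)
        m = models["y1_ee_pct"]
        c = m.coefficients
        for _ in range(100):
            x1, x2, x3 = rng.uniform(-1.7, 1.7, size=3)
            manual = (
                c["b0"] + c["b1"] * x1 + c["b2"] * x2 + c["b3"] * x3
                + c["b12"] * x1 * x2 + c["b13"] * x1 * x3 + c["b23"] * x2 * x3
                + c["b11"] * x1**2 + c["b22"] * x2**2 + c["b33"] * x3**2
            )
            assert predict_response(m, [x1, x2, x3]) == pytest.approx(
                manual, rel=1e-12
            )

    def test_shape_check(self, models):
        with pytest.raises(ValueError):
            predict_response(models["y1_ee_pct"], [0.0, 0.0])


class TestDiagnostics:
    def test_reported_table_values(self, models):
        d1 = compute_diagnostics(models["y1_ee_pct"])
        assert d1.adj_R2 == pytest.approx(0.9901, abs=5e-4)
        assert d1.pred_R2 == pytest.approx(0.9613, abs=5e-4)
        assert d1.CV_pct == pytest.approx(2.40, abs=0.01)
        assert d1.adeq_precision == pytest.approx(39.06, abs=0.05)
        d2 = compute_diagnostics(models["y2_buoyancy_h"])
        assert d2.adj_R2 == pytest.approx(0.9750, abs=5e-4)
        assert d2.pred_R2 == pytest.approx(0.9167, abs=5e-4)
        assert d2.CV_pct == pytest.approx(7.20, abs=0.01)
        d3 = compute_diagnostics(models["y3_q6h_pct"])
        assert d3.adj_R2 == pytest.approx(0.9830, abs=5e-4)
        assert d3.pred_R2 == pytest.approx(0.9434, abs=5e-4)
        assert d3.CV_pct == pytest.approx(3.82, abs=0.01)

    def test_model_p_values_within_reported_bounds(self, models):
        # the study reports p only as bounds (< 1e-4, < 2e-4)
        assert compute_diagnostics(models["y1_ee_pct"]).p_model < 1e-4
        assert compute_diagnostics(models["y2_buoyancy_h"]).p_model < 2e-4
        assert compute_diagnostics(models["y3_q6h_pct"]).p_model < 1e-4

    def test_r2_ordering_invariants(self, models):
        for m in models.values():
            d = compute_diagnostics(m)
            assert d.pred_R2 <= d.R2
            assert d.adj_R2 <= d.R2
            assert d.PRESS >= float(m.residuals @ m.residuals)
            assert d.CV_pct >= 0

    def test_noiseless_fit_r2_is_one(self):
        d = build_ccd(datasets.FACTORS, n_center=3)
        d = gen_ccd_responses(d, datasets.REFERENCE_COEFFICIENTS, 0.0, seed=0)
        diag = compute_diagnostics(fit_quadratic_rsm(d, "y2_buoyancy_h"))
        assert diag.R2 == pytest.approx(1.0, abs=1e-12)
        assert diag.adj_R2 == pytest.approx(1.0, abs=1e-12)

    def test_dropping_quadratic_terms_never_increases_r2(self, design):
        # nested OLS: the reduced model's SSE can only grow
        for name in datasets.RESPONSE_NAMES:
            y = design.response(name)
            X_full = model_matrix(design.coded)
            X_red = X_full[:, :7]  # drop the three pure-quadratic columns
            sse = lambda X: float(
                ((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum()
            )
            sst = float(((y - y.mean()) ** 2).sum())
            assert 1 - sse(X_red) / sst <= 1 - sse(X_full) / sst + 1e-12


class TestPRESS:
    @pytest.mark.parametrize("response", datasets.RESPONSE_NAMES)
    def test_loo_oracle_matches_hat_shortcut(self, design, models, response):
        press_hat = compute_diagnostics(models[response]).PRESS
        press_loo = press_by_loo(design, response)
        assert press_loo == pytest.approx(press_hat, rel=1e-8)

    def test_saturated_design_raises(self):
        # exactly p distinct points: deleting any one makes refits singular
        d = build_ccd(datasets.FACTORS[:2], n_center=1)  # 9 runs, 6 params
        rng = np.random.default_rng(0)
        d = d.with_responses({"y": rng.uniform(size=9)})
        # shrink to 6 rows = 6 params (saturated)
        from beadopt.doe import DesignTable

        sat = DesignTable(
            factors=d.factors, coded=d.coded[:6], responses={"y": d.response("y")[:6]}
        )
        with pytest.raises(ValueError):
            press_by_loo(sat, "y")

    def test_duplicate_center_points_keep_press_finite(self, design):
        assert np.isfinite(press_by_loo(design, "y1_ee_pct"))


class TestParameterRecoveryUnderNoise:
    def test_b1_unbiased_at_reported_cv(self):
        # 200 Monte-Carlo replicates at the reported 2.4% CV: the mean
        # estimate of the alginate linear effect must sit within 2 MC
        # standard errors of truth
        d = build_ccd(datasets.FACTORS, n_center=3)
        truth = datasets.REFERENCE_COEFFICIENTS["y1_ee_pct"]
        est = []
        for rep in range(200):
            dd = gen_ccd_responses(
                d, {"y1_ee_pct": truth}, cv_pct=2.4, seed=10_000 + rep
            )
            est.append(
                fit_quadratic_rsm(dd, "y1_ee_pct").coefficients["b1"]
            )
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - truth["b1"]) <= 2 * mc_se
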