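"""Penalized binomial GAM: fitting, GCV, inference, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from firegam.gam import (
    ModelSpec,
    SmoothTerm,
    TensorTerm,
    SeparationError,
    deviance_residuals,
    fit_binomial_gam,
    fit_summaries,
    gcv_score,
    predict,
    smooth_confidence_bands,
    smooth_term_test,
    term_pvalues,
)


def _frame(y, n, **cov):
    return pd.DataFrame({"visits": np.asarray(y, float), "population": np.asarray(n, float), **cov})


class TestGlmCore:
    def test_intercept_only_half(self):
        fit = fit_binomial_gam(ModelSpec(), _frame(np.full(25, 50), np.full(25, 100)))
        assert np.isclose(fit.coef[0], 0.0, atol=1e-10)
        assert np.allclose(fit.fitted_p, 0.5)

    def test_binary_covariate_equals_log_odds_ratio(self):
        # aggregated 2x2 table: OR = (a*d)/(b*c)
        y = np.array([30.0, 28.0, 55.0, 52.0])
        n = np.array([100.0, 100.0, 100.0, 100.0])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        a, b = 55 + 52, 45 + 48
        c, d = 30 + 28, 70 + 72
        fit = fit_binomial_gam(ModelSpec(indicator_terms=("x",)), _frame(y, n, x=x))
        assert np.isclose(fit.coefficients["x"], np.log((a * d) / (b * c)), atol=1e-8)

    def test_matches_glm_oracle(self, small_glm_frame):
        import statsmodels.api as sm

        fit = fit_binomial_gam(ModelSpec(linear_terms=("x",), indicator_terms=("ind",)), small_glm_frame)
        X = sm.add_constant(small_glm_frame[["x", "ind"]].to_numpy())
        y = small_glm_frame["visits"].to_numpy()
        n = small_glm_frame["population"].to_numpy()
        ref = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef, ref.params, rtol=1e-6)
        assert np.allclose(np.sqrt(np.diag(fit.cov)), ref.bse, rtol=1e-5)

    def test_affine_rescaling_invariance(self, small_glm_frame):
        fit = fit_binomial_gam(ModelSpec(linear_terms=("x",)), small_glm_frame)
        scaled = small_glm_frame.assign(x=lambda d: 3.5 * d["x"] - 2.0)
        fit2 = fit_binomial_gam(ModelSpec(linear_terms=("x",)), scaled)
        assert np.isclose(fit2.coefficients["x"], fit.coefficients["x"] / 3.5, rtol=1e-8)
        assert np.allclose(fit2.fitted_p, fit.fitted_p, atol=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_binomial_gam(ModelSpec(), _frame([5.0], [0.0]))
        with pytest.raises(ValueError):
            fit_binomial_gam(ModelSpec(), _frame([11.0], [10.0]))
        with pytest.raises(ValueError):
            ModelSpec(linear_terms=("x",), smooth_terms=(SmoothTerm("x"),))

    def test_non_binary_indicator_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            fit_binomial_gam(
                ModelSpec(indicator_terms=("x",)), _frame([5.0, 6.0], [10.0, 10.0], x=[0.5, 1.0])
            )

    def test_separation_diagnosed(self):
        df = _frame([0.0, 0.0, 10.0, 10.0], [10.0] * 4, x=[-2.0, -1.0, 1.0, 2.0])
        with pytest.raises(SeparationError):
            fit_binomial_gam(ModelSpec(linear_terms=("x",)), df)


@pytest.fixture(scope="module")
def curved():
    rng = np.random.default_rng(21)
    n = 250
    x = rng.uniform(-1, 1, n)
    eta = -3.0 + 1.3 * x**2
    y = rng.binomial(8000, expit(eta)).astype(float)
    return _frame(y, np.full(n, 8000.0), x=x)


class TestSmoothFitting:
    def test_gcv_fit_tracks_curved_truth(self, curved):
        fit = fit_binomial_gam(ModelSpec(smooth_terms=(SmoothTerm("x", 10),)), curved)
        est = smooth_confidence_bands(fit, "s(x)")
        truth = 1.3 * est.grid**2
        truth -= (1.3 * curved["x"] ** 2).mean()
        assert np.max(np.abs(est.fit - truth)) < 0.06
        assert 2.0 < fit.edf_by_term["s(x)"] < 9.0

    def test_infinite_lambda_gives_best_straight_line(self, curved):
        spec = ModelSpec(smooth_terms=(SmoothTerm("x", 10),))
        fit = fit_binomial_gam(spec, curved, lambdas=[1e12])
        est = smooth_confidence_bands(fit, "s(x)", n_grid=60)
        lin = fit_binomial_gam(ModelSpec(linear_terms=("x",)), curved)
        slope = lin.coefficients["x"]
        line = slope * (est.grid - curved["x"].mean())
        assert np.max(np.abs(est.fit - line)) < 1e-4
        assert np.isclose(fit.edf_by_term["s(x)"], 1.0, atol=1e-3)

    def test_gcv_score_reorder_invariant(self, curved):
        spec = ModelSpec(smooth_terms=(SmoothTerm("x", 10),))
        fit = fit_binomial_gam(spec, curved)
        shuffled = curved.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_binomial_gam(spec, shuffled, lambdas=fit.lambdas)
        assert np.isclose(fit.gcv, fit2.gcv, rtol=1e-8)

    def test_gcv_score_formula(self):
        assert np.isclose(gcv_score(200.0, 100, 10.0), 100 * 200.0 / 90.0**2)
        assert gcv_score(200.0, 100, 100.0) == np.inf

    def test_smooth_statistic_nonnegative(self, curved):
        fit = fit_binomial_gam(ModelSpec(smooth_terms=(SmoothTerm("x", 10),)), curved)
        stat, dof, p = smooth_term_test(fit, "s(x)")
        assert stat >= 0.0 and dof >= 1 and 0.0 <= p <= 1.0


class TestPredictAndBands:
    def test_prediction_basics(self, small_glm_frame):
        fit = fit_binomial_gam(ModelSpec(linear_terms=("x",)), small_glm_frame)
        out = predict(fit, small_glm_frame)
        assert np.allclose(out["prob"], fit.fitted_p, atol=1e-12)
        # delta method: se_p = p(1-p) se_eta, so at eta=0, se_p = se_eta/4
        at_zero = small_glm_frame.head(1).assign(
            x=-fit.coef[0] / fit.coefficients["x"]
        )
        o = predict(fit, at_zero)
        assert np.isclose(o["prob"][0], 0.5, atol=1e-10)
        assert np.isclose(o["se_prob"][0], 0.25 * o["se_eta"][0], rtol=1e-10)

    def test_unknown_covariate_rejected(self, small_glm_frame):
        fit = fit_binomial_gam(ModelSpec(linear_terms=("x",)), small_glm_frame)
        with pytest.raises(KeyError, match="x"):
            predict(fit, small_glm_frame.drop(columns=["x"]))

    def test_bands_symmetric_and_widen_in_sparse_gap(self):
        rng = np.random.default_rng(4)
        # dense data on [-1,-0.2] and [0.2,1], sparse gap in the middle
        x = np.concatenate([rng.uniform(-1, -0.2, 150), rng.uniform(0.2, 1, 150), [0.0]])
        eta = -2.5 + 0.8 * np.sin(2 * x)
        y = rng.binomial(4000, expit(eta)).astype(float)
        df = _frame(y, np.full(len(x), 4000.0), x=x)
        fit = fit_binomial_gam(ModelSpec(smooth_terms=(SmoothTerm("x", 10),)), df)
        est = smooth_confidence_bands(fit, "s(x)")
        assert np.allclose((est.lower + est.upper) / 2, est.fit, atol=1e-10)
        assert np.allclose(est.upper - est.fit, 1.96 * est.se, atol=1e-10)
        gap = (est.grid > -0.18) & (est.grid < 0.18)
        dense = (est.grid < -0.3) | (est.grid > 0.3)
        assert est.se[gap].mean() > est.se[dense].mean()

    def test_heavy_smoothing_collapses_bands(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-1, 1, 200)
        y = rng.binomial(3000, expit(-2.5 + 0.5 * x)).astype(float)
        df = _frame(y, np.full(200, 3000.0), x=x)
        spec = ModelSpec(smooth_terms=(SmoothTerm("x", 10),))
        rough = fit_binomial_gam(spec, df, lambdas=[1e-8])
        smooth = fit_binomial_gam(spec, df, lambdas=[1e12])
        b_r = smooth_confidence_bands(rough, "s(x)")
        b_s = smooth_confidence_bands(smooth, "s(x)")
        assert b_s.se.max() < b_r.se.max()


class TestSummaries:
    def test_intercept_only_zero_deviance_explained(self):
        rng = np.random.default_rng(1)
        y = rng.binomial(100, 0.3, 40).astype(float)
        fit = fit_binomial_gam(ModelSpec(), _frame(y, np.full(40, 100.0)))
        assert np.isclose(fit_summaries(fit)["deviance_explained"], 0.0, atol=1e-9)

    def test_perfect_fit_full_deviance_explained(self):
        y = np.array([30.0] * 10 + [70.0] * 10)
        g = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_binomial_gam(ModelSpec(indicator_terms=("g",)), _frame(y, np.full(20, 100.0), g=g))
        assert fit_summaries(fit)["deviance_explained"] > 0.999999

    def test_squared_residuals_sum_to_deviance(self, subregion_fit):
        r = deviance_residuals(subregion_fit)
        assert np.isclose(np.sum(r**2), subregion_fit.deviance, rtol=1e-8)

    def test_deviance_below_null(self, subregion_fit):
        assert subregion_fit.deviance <= subregion_fit.null_deviance
        for term in ("s(anthro_pm25)", "te(mean_rh,min_temp)"):
            edf = subregion_fit.edf_by_term[term]
            assert 1.0 <= edf <= 25.0

    def test_term_pvalue_table_complete(self, subregion_fit, subregion_spec):
        pv = term_pvalues(subregion_fit)
        assert set(pv) == set(subregion_spec.term_names())
        assert all(0.0 <= p <= 1.0 for p in pv.values())
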