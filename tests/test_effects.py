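"""Odds-effect transforms, effects table, surface export, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from firegam.effects import (
    build_effects_table,
    export_surfaces,
    odds_effect_continuous,
    odds_effect_indicator,
    odds_effect_intercept,
    residual_diagnostics,
)
from firegam.gam import ModelSpec, fit_binomial_gam
from firegam.synth import SyntheticConfig, default_truth, simulate_dataset


class TestOddsTransforms:
    def test_intercept_published_values(self):
        # county and sub-region baseline odds from the printed intercepts
        assert np.isclose(odds_effect_intercept(-9.45), 7.87e-5, rtol=5e-3)
        assert np.isclose(odds_effect_intercept(-7.76), 4.27e-4, rtol=5e-3)
        assert odds_effect_intercept(0.0) == 1.0

    def test_continuous_fire_pm_peak(self):
        # OR 1.00093/unit over 0..587.08 ug/m3 -> ~1.73 at the peak
        lo, hi = odds_effect_continuous(1.00093, (0.0, 587.08))
        assert lo == 1.0
        assert np.isclose(hi, 1.7259, atol=5e-4)
        assert abs(hi - 1.72) < 0.02  # printed-table agreement

    def test_continuous_income_range(self):
        lo, hi = odds_effect_continuous(0.0087, (0.30, 0.55))
        assert np.isclose(lo, 0.24, atol=0.005)
        assert np.isclose(hi, 0.07, atol=0.005)

    def test_unit_odds_ratio_flat(self):
        assert odds_effect_continuous(1.0, (-3.0, 9.0)) == (1.0, 1.0)

    def test_multiplicative_in_range(self):
        full = odds_effect_continuous(1.004, (0.0, 50.0))[1]
        lo = odds_effect_continuous(1.004, (0.0, 20.0))[1]
        hi_part = odds_effect_continuous(1.004, (20.0, 50.0))
        assert np.isclose(full / lo, hi_part[1] / hi_part[0], rtol=1e-12)

    def test_indicator_percent_changes(self):
        assert odds_effect_indicator(1.172) == (1.172, 17)
        assert odds_effect_indicator(1.072) == (1.072, 7)
        assert odds_effect_indicator(1.0) == (1.0, 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            odds_effect_continuous(-1.0, (0, 1))
        with pytest.raises(ValueError):
            odds_effect_indicator(0.0)
        with pytest.raises(ValueError):
            odds_effect_intercept(float("nan"))


class TestEffectsTable:
    def test_published_subregion_column(self):
        """Injecting the published sub-region coefficients (taking logs of
        the odds-scale estimates) reproduces the published odds-effect
        column at 2-decimal rounding."""
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "visits": [40.0] * 10,
                "population": [100000.0] * 10,
                "fire_pm": rng.uniform(0, 587.08, 10),
                "prop_income_gt50k": rng.uniform(0.30, 0.55, 10),
                "is_monday": [1.0, 0.0] * 5,
            }
        )
        spec = ModelSpec(linear_terms=("fire_pm", "prop_income_gt50k"), indicator_terms=("is_monday",))
        fit = fit_binomial_gam(spec, frame, max_iter=1)
        # overwrite with published coefficients; the table is a pure transform
        fit.coef[:] = [
            -7.76,
            np.log(1.00093),
            np.log(0.0087),
            np.log(1.174),
        ]
        tbl = build_effects_table(
            fit, {"fire_pm": (0.0, 587.08), "prop_income_gt50k": (0.30, 0.55)}
        ).set_index("term")
        assert np.isclose(tbl.loc["intercept", "odds_hi"], 4.27e-4, rtol=5e-3)
        assert tbl.loc["fire_pm", "odds_lo"] == 1.0
        assert abs(tbl.loc["fire_pm", "odds_hi"] - 1.72) <= 0.011
        assert tbl.loc["prop_income_gt50k", "odds_lo"] == 0.24
        assert tbl.loc["prop_income_gt50k", "odds_hi"] == 0.07
        assert tbl.loc["is_monday", "percent_change"] == 17

    def test_intercept_only_single_row(self):
        frame = pd.DataFrame({"visits": [50.0] * 5, "population": [100.0] * 5})
        fit = fit_binomial_gam(ModelSpec(), frame)
        tbl = build_effects_table(fit, {})
        assert len(tbl) == 1 and tbl.iloc[0]["term"] == "intercept"

    def test_zero_coefficients_unit_multipliers(self):
        frame = pd.DataFrame(
            {"visits": [50.0] * 8, "population": [100.0] * 8,
             "x": np.arange(8.0), "flag": [0.0, 1.0] * 4}
        )
        fit = fit_binomial_gam(ModelSpec(linear_terms=("x",), indicator_terms=("flag",)), frame)
        fit.coef[:] = 0.0
        tbl = build_effects_table(fit, {"x": (0.0, 7.0)}).set_index("term")
        assert tbl.loc["intercept", "odds_hi"] == 1.0
        assert tbl.loc["x", "odds_lo"] == 1.0 and tbl.loc["x", "odds_hi"] == 1.0
        assert tbl.loc["flag", "percent_change"] == 0

    def test_missing_range_rejected(self, subregion_fit):
        with pytest.raises(KeyError, match="fire_pm"):
            build_effects_table(subregion_fit, {})

    def test_roundtrip_recovers_truth_multipliers(self, subregion_fit):
        """End-to-end: fitting data generated from the known truth reproduces
        the truth's odds multipliers within estimation error.  This is a
        single-seed smoke check at 3 se; the multi-seed 2-se coverage study
        lives in the acceptance suite."""
        for term, target in [
            ("is_monday", 1.174),
            ("is_tuesday", 1.072),
            ("is_sr3", 0.512),
            ("is_sr6", 1.209),
        ]:
            est = subregion_fit.coefficients[term]
            se = subregion_fit.se(term)
            assert abs(est - np.log(target)) < 3 * se


class TestSurfacesAndDiagnostics:
    def test_univariate_export_matches_bands(self, subregion_fit):
        from firegam.gam import smooth_confidence_bands

        surf = export_surfaces(subregion_fit, ["s(anthro_pm25)"], resolution=40)["s(anthro_pm25)"]
        est = smooth_confidence_bands(subregion_fit, "s(anthro_pm25)", grid=surf["x"].to_numpy())
        assert np.allclose(surf["odds"], np.exp(est.fit))
        assert len(surf) == 40

    def test_truth_surface_argmax_high_humidity_moderate_temp(self):
        truth = default_truth()
        rh = np.linspace(6, 79, 60)
        tm = np.linspace(36, 72, 60)
        R, T = np.meshgrid(rh, tm, indexing="ij")
        g = truth.interaction_surface(R.ravel(), T.ravel()).reshape(60, 60)
        i, j = np.unravel_index(np.argmax(g), g.shape)
        assert rh[i] > 60  # high humidity
        assert 45 < tm[j] < 65  # moderate minimum temperature

    def test_fitted_tensor_export_resolution_and_term_errors(self, subregion_fit):
        surf = export_surfaces(subregion_fit, resolution=25)
        te = surf["te(mean_rh,min_temp)"]
        assert len(te) == 625
        with pytest.raises(KeyError):
            export_surfaces(subregion_fit, ["s(nope)"])

    def test_residual_diagnostics_consistency(self, subregion_fit, default_dataset):
        diag = residual_diagnostics(subregion_fit, default_dataset["model_frame"])
        assert np.isclose(diag["sum_squared"], subregion_fit.deviance, rtol=1e-8)
        assert set(diag["lag1_autocorrelation"]) == {f"SR{i}" for i in range(1, 7)}

    def test_true_model_residuals_are_white(self):
        """Residuals of the correctly specified model on its own data show
        no lag-1 autocorrelation beyond sampling noise in most seeds."""
        from firegam.gam import SmoothTerm, TensorTerm

        spec = ModelSpec(
            linear_terms=("fire_pm", "prop_income_gt50k", "prop_age_lt24"),
            indicator_terms=("is_monday", "is_tuesday", "is_sr3", "is_sr6"),
            smooth_terms=(SmoothTerm("anthro_pm25", 10),),
            tensor_terms=(TensorTerm("mean_rh", "min_temp", 5, 5),),
        )
        bound = 2.0 / np.sqrt(121)
        ok = total = 0
        for seed in range(5):
            ds = simulate_dataset(SyntheticConfig(seed=seed))
            fit = fit_binomial_gam(spec, ds["model_frame"])
            diag = residual_diagnostics(fit, ds["model_frame"])
            for r in diag["lag1_autocorrelation"].values():
                total += 1
                if abs(r) <= bound:
                    ok += 1
        assert ok / total >= 0.8
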