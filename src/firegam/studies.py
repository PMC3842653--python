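"""Seeded simulation studies validating the fitting and selection machinery.

Each study generates data from a known truth, runs the estimator under test,
and reports a rate or error summary.  They are used by the test suite and the
acceptance script; the analysis drivers call them with the same defaults.

Study-specific generating truths are deliberately minimal (e.g. no
interaction surface when the question is about a single univariate smooth):
each study isolates one property of the machinery.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import default_model_spec
from .gam import (
    ModelSpec,
    SmoothTerm,
    fit_binomial_gam,
    smooth_term_pvalue,
)
from .selection import backward_eliminate
from .synth import (
    COUNTY_REGION,
    SyntheticConfig,
    TruthParameters,
    default_truth,
    simulate_dataset,
    _anthro_smooth,
)

__all__ = [
    "oracle_comparison",
    "parameter_recovery",
    "noise_covariate_removal",
    "linear_smooth_demotion",
    "smooth_test_type1",
    "smooth_test_power",
    "gcv_vs_forced_linear",
]


def _county_config(seed: int, **kw) -> SyntheticConfig:
    return SyntheticConfig(regions=(COUNTY_REGION,), seed=seed, **kw)


def _county_truth(**overrides) -> TruthParameters:
    """County-scale truth: intercept matched to the county count level, no
    spatial/demographic terms."""
    base = default_truth()
    kw = dict(
        intercept=-9.45,
        linear_coefs={"fire_pm": np.log(1.0010)},
        indicator_coefs={"is_monday": np.log(1.172), "is_tuesday": np.log(1.075)},
        smooth_functions={"anthro_pm25": _anthro_smooth()},
        interaction_surface=None,
        kernel=base.kernel,
    )
    kw.update(overrides)
    return TruthParameters(**kw)


_COUNTY_POP = {"county": 3_000_000}


def oracle_comparison(n_datasets: int = 20, seed: int = 0) -> dict:
    """Smooth-free GAM fits versus an independent standard logistic GLM.

    Random small binomial datasets; returns the maximum relative difference
    in coefficients and standard errors across datasets.  Requires
    statsmodels (the oracle).
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    import pandas as pd

    worst_coef = worst_se = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(60, 120))
        x1, x2 = rng.normal(size=n), rng.uniform(-1, 1, n)
        ind = (rng.random(n) < 0.4).astype(float)
        trials = rng.integers(30, 500, n).astype(float)
        eta = rng.normal(-2.0, 0.3) + 0.5 * x1 - 0.8 * x2 + 0.3 * ind
        p = 1.0 / (1.0 + np.exp(-eta))
        y = rng.binomial(trials.astype(int), p).astype(float)
        df = pd.DataFrame({"visits": y, "population": trials, "x1": x1, "x2": x2, "ind": ind})
        spec = ModelSpec(linear_terms=("x1", "x2"), indicator_terms=("ind",))
        fit = fit_binomial_gam(spec, df, tol=1e-12, max_iter=200)
        X = sm.add_constant(np.column_stack([x1, x2, ind]))
        ref = sm.GLM(np.column_stack([y, trials - y]), X, family=sm.families.Binomial()).fit()
        denom = np.maximum(np.abs(ref.params), 1e-8)
        worst_coef = max(worst_coef, float(np.max(np.abs(fit.coef - ref.params) / denom)))
        se = np.sqrt(np.diag(fit.cov))
        worst_se = max(worst_se, float(np.max(np.abs(se - ref.bse) / ref.bse)))
    return {"max_rel_coef_diff": worst_coef, "max_rel_se_diff": worst_se, "n_datasets": n_datasets}


def parameter_recovery(n_reps: int = 50, seed: int = 0) -> dict:
    """Refit the correctly specified sub-region GAM on its own simulated data.

    Returns, per reported coefficient, the fraction of replicates whose
    estimate lies within 2 estimated standard errors of the truth.
    """
    truth = default_truth()
    targets = {
        "intercept": truth.intercept,
        "fire_pm": truth.linear_coefs["fire_pm"],
        "is_monday": truth.indicator_coefs["is_monday"],
        "is_tuesday": truth.indicator_coefs["is_tuesday"],
    }
    spec = ModelSpec(
        linear_terms=("fire_pm", "prop_income_gt50k", "prop_age_lt24"),
        indicator_terms=("is_monday", "is_tuesday", "is_sr3", "is_sr6"),
        smooth_terms=(SmoothTerm("anthro_pm25", 10),),
        tensor_terms=(("mean_rh", "min_temp", 5, 5),),
    )
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    hits = {k: 0 for k in targets}
    for r in range(n_reps):
        ds = simulate_dataset(SyntheticConfig(seed=int(base + r)), truth=truth)
        fit = fit_binomial_gam(spec, ds["model_frame"])
        est = fit.coefficients
        for k, tv in targets.items():
            se = fit.intercept_se if k == "intercept" else fit.se(k)
            if abs(est[k] - tv) <= 2.0 * se:
                hits[k] += 1
    return {k: v / n_reps for k, v in hits.items()} | {"n_reps": n_reps}


def noise_covariate_removal(n_reps: int = 100, seed: int = 0, alpha: float = 0.05) -> dict:
    """Backward elimination should drop an appended pure-noise covariate."""
    truth = _county_truth()
    spec = ModelSpec(
        linear_terms=("fire_pm", "noise"),
        indicator_terms=("is_monday", "is_tuesday"),
        smooth_terms=(SmoothTerm("anthro_pm25", 8),),
    )
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    removed = 0
    for r in range(n_reps):
        rep_seed = int(base + r)
        ds = simulate_dataset(_county_config(rep_seed), truth=truth, populations=_COUNTY_POP)
        frame = ds["model_frame"].copy()
        frame["noise"] = np.random.default_rng(rep_seed + 7_000_000).normal(size=len(frame))
        trace = backward_eliminate(spec, frame, alpha=alpha)
        if not trace.failed and "noise" in trace.removed:
            removed += 1
    return {"removal_rate": removed / n_reps, "n_reps": n_reps}


def linear_smooth_demotion(n_reps: int = 100, seed: int = 0, alpha: float = 0.05) -> dict:
    """A smooth whose true effect is linear should end up as a linear term."""
    truth = _county_truth(smooth_functions={}, linear_coefs={"fire_pm": np.log(1.0010), "anthro_pm25": 0.12})
    spec = ModelSpec(
        linear_terms=("fire_pm",),
        indicator_terms=("is_monday", "is_tuesday"),
        smooth_terms=(SmoothTerm("anthro_pm25", 8),),
    )
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    demoted = 0
    for r in range(n_reps):
        ds = simulate_dataset(_county_config(int(base + r)), truth=truth, populations=_COUNTY_POP)
        trace = backward_eliminate(spec, ds["model_frame"], alpha=alpha)
        if trace.failed:
            continue
        final = trace.final_spec
        if "anthro_pm25" in final.linear_terms and "s(anthro_pm25)" not in [s.name for s in final.smooth_terms]:
            demoted += 1
    return {"demotion_rate": demoted / n_reps, "n_reps": n_reps}


def smooth_test_type1(n_reps: int = 200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the approximate chi-square smooth test under a null
    smooth (true anthropogenic-PM effect identically zero)."""
    truth = _county_truth(smooth_functions={})
    spec = ModelSpec(
        linear_terms=("fire_pm",),
        indicator_terms=("is_monday", "is_tuesday"),
        smooth_terms=(SmoothTerm("anthro_pm25", 8),),
    )
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    rejections = 0
    for r in range(n_reps):
        ds = simulate_dataset(_county_config(int(base + r)), truth=truth, populations=_COUNTY_POP)
        fit = fit_binomial_gam(spec, ds["model_frame"])
        if smooth_term_pvalue(fit, "s(anthro_pm25)") < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def smooth_test_power(n_reps: int = 50, seed: int = 0, threshold: float = 1e-3) -> dict:
    """Power of the smooth test against the default curved anthro-PM effect."""
    truth = _county_truth()
    spec = ModelSpec(
        linear_terms=("fire_pm",),
        indicator_terms=("is_monday", "is_tuesday"),
        smooth_terms=(SmoothTerm("anthro_pm25", 8),),
    )
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    hits = 0
    for r in range(n_reps):
        ds = simulate_dataset(_county_config(int(base + r)), truth=truth, populations=_COUNTY_POP)
        fit = fit_binomial_gam(spec, ds["model_frame"])
        if smooth_term_pvalue(fit, "s(anthro_pm25)") < threshold:
            hits += 1
    return {"detection_rate": hits / n_reps, "n_reps": n_reps}


def gcv_vs_forced_linear(n_reps: int = 20, seed: int = 0) -> dict:
    """Out-of-sample deviance of the GCV-selected smooth versus a forced
    linear fit, on data with a strongly curved effect.  Returns the fraction
    of replicates where the GCV fit predicts better."""
    import pandas as pd
    from .gam import _binom_deviance
    from scipy.special import expit

    rng_master = np.random.SeedSequence(seed)
    base = rng_master.generate_state(1)[0] % (2**31)
    wins = 0
    for r in range(n_reps):
        rng = np.random.default_rng(int(base + r))
        n = 240
        x = rng.uniform(-1, 1, n)
        eta = -4.0 + 1.5 * x**2
        trials = np.full(n, 20_000.0)
        y = rng.binomial(20_000, expit(eta)).astype(float)
        df = pd.DataFrame({"visits": y, "population": trials, "x": x})
        train, test = df.iloc[: n // 2], df.iloc[n // 2 :]
        smooth_fit = fit_binomial_gam(ModelSpec(smooth_terms=(SmoothTerm("x", 10),)), train)
        linear_fit = fit_binomial_gam(ModelSpec(linear_terms=("x",)), train)
        yt = test["visits"].to_numpy()
        nt = test["population"].to_numpy()
        from .gam import predict

        d_s = _binom_deviance(yt, nt, np.clip(predict(smooth_fit, test)["prob"], 1e-12, 1 - 1e-12)).sum()
        d_l = _binom_deviance(yt, nt, np.clip(predict(linear_fit, test)["prob"], 1e-12, 1 - 1e-12)).sum()
        if d_s < d_l:
            wins += 1
    return {"gcv_win_rate": wins / n_reps, "n_reps": n_reps}
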