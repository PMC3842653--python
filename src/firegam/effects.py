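"""Odds-effect summaries, surface exports and residual diagnostics.

Coefficients live on the log-odds scale internally; reporting transforms them
to multiplicative odds effects over each predictor's observed dynamic range:

* intercept            -> baseline odds  exp(beta0)
* indicator            -> static odds multiplier exp(beta), percent change
* continuous (linear)  -> odds ratio per unit raised to the range endpoints,
                          OR^lo .. OR^hi
* smooth / tensor      -> no single multiplier; exported as odds-scale grids

Published tables often print linear coefficients already exponentiated (an
odds ratio per unit, e.g. 1.0010); take logs before injecting such values as
log-odds coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import FittedModel, deviance_residuals, smooth_confidence_bands

__all__ = [
    "odds_effect_intercept",
    "odds_effect_continuous",
    "odds_effect_indicator",
    "build_effects_table",
    "export_surfaces",
    "residual_diagnostics",
]


def odds_effect_intercept(beta0: float) -> float:
    """Baseline odds exp(beta0)."""
    if not np.isfinite(beta0):
        raise ValueError("intercept must be finite")
    return float(np.exp(beta0))


def odds_effect_continuous(or_per_unit: float, value_range: tuple) -> tuple:
    """Odds effect of a linear term over its observed range.

    Returns ``(or_per_unit**lo, or_per_unit**hi)`` — the multiplicative odds
    change when the covariate sits at each end of its dynamic range.
    """
    if or_per_unit <= 0:
        raise ValueError("odds ratio per unit must be > 0")
    lo, hi = value_range
    return (float(or_per_unit**lo), float(or_per_unit**hi))


def odds_effect_indicator(or_when_true: float) -> tuple:
    """Static odds multiplier and integer percent change when the flag is on."""
    if or_when_true <= 0:
        raise ValueError("odds ratio must be > 0")
    return float(or_when_true), int(round(100.0 * (or_when_true - 1.0)))


def build_effects_table(fitted: FittedModel, observed_ranges: dict) -> pd.DataFrame:
    """Per-term odds-effect table over observed covariate ranges.

    ``observed_ranges`` maps each continuous (linear) term to its (lo, hi)
    observed range.  Smooth/tensor terms carry no single multiplier and are
    reported by reference to their exported surfaces.
    """
    rows = [
        {
            "term": "intercept",
            "role": "intercept",
            "range_lo": np.nan,
            "range_hi": np.nan,
            "odds_lo": np.nan,
            "odds_hi": round(odds_effect_intercept(fitted.coef[0]), 10),
            "percent_change": np.nan,
        }
    ]
    for name, blk in fitted.design.blocks.items():
        if blk.kind == "linear":
            if name not in observed_ranges:
                raise KeyError(f"no observed range supplied for continuous term {name!r}")
            lo, hi = observed_ranges[name]
            o_lo, o_hi = odds_effect_continuous(np.exp(fitted.coef[blk.sl][0]), (lo, hi))
            rows.append(
                {"term": name, "role": "continuous", "range_lo": lo, "range_hi": hi,
                 "odds_lo": round(o_lo, 2), "odds_hi": round(o_hi, 2), "percent_change": np.nan}
            )
        elif blk.kind == "indicator":
            mult, pct = odds_effect_indicator(np.exp(fitted.coef[blk.sl][0]))
            rows.append(
                {"term": name, "role": "indicator", "range_lo": 0.0, "range_hi": 1.0,
                 "odds_lo": 1.0, "odds_hi": round(mult, 2), "percent_change": pct}
            )
        else:
            rows.append(
                {"term": name, "role": blk.kind, "range_lo": np.nan, "range_hi": np.nan,
                 "odds_lo": np.nan, "odds_hi": np.nan, "percent_change": np.nan}
            )
    return pd.DataFrame(rows)


def export_surfaces(fitted: FittedModel, terms=None, resolution: int = 40) -> dict:
    """Odds-scale grids for plotting smooths (rugplot data) and tensors.

    Univariate smooths export columns (x, fit, se, odds, odds_lo, odds_hi);
    tensor terms export a long-format rectangular grid with columns
    (a, b, fit, odds).  Grids span the observed (knot) ranges with exactly
    ``resolution`` points per axis.
    """
    blocks = fitted.design.blocks
    if terms is None:
        terms = [n for n, b in blocks.items() if b.kind in ("smooth", "tensor")]
    out = {}
    for term in terms:
        if term not in blocks or blocks[term].kind not in ("smooth", "tensor"):
            raise KeyError(f"no smooth/tensor term named {term!r}")
        blk = blocks[term]
        if blk.kind == "smooth":
            est = smooth_confidence_bands(fitted, term, n_grid=resolution)
            out[term] = pd.DataFrame(
                {
                    "x": est.grid,
                    "fit": est.fit,
                    "se": est.se,
                    "odds": np.exp(est.fit),
                    "odds_lo": np.exp(est.lower),
                    "odds_hi": np.exp(est.upper),
                }
            )
        else:
            tp = blk.basis
            ga = np.linspace(tp.margin_a.knots[0], tp.margin_a.knots[-1], resolution)
            gb = np.linspace(tp.margin_b.knots[0], tp.margin_b.knots[-1], resolution)
            A, B = np.meshgrid(ga, gb, indexing="ij")
            T = tp.evaluate(A.ravel(), B.ravel())[:, 1:] - blk.center
            f = T @ fitted.coef[blk.sl]
            out[term] = pd.DataFrame(
                {
                    tp.margin_a.covariate: A.ravel(),
                    tp.margin_b.covariate: B.ravel(),
                    "fit": f,
                    "odds": np.exp(f),
                }
            )
    return out


def residual_diagnostics(fitted: FittedModel, data: pd.DataFrame) -> dict:
    """Deviance-residual diagnostics per region.

    Returns the residual series aligned to region/date, each region's lag-1
    autocorrelation, and a Shapiro-Wilk normality summary.  Purely
    descriptive — nothing here gates the fit.
    """
    resid = deviance_residuals(fitted)
    series = pd.DataFrame(
        {
            "region_id": data["region_id"].to_numpy() if "region_id" in data else "all",
            "date": data["date"].to_numpy() if "date" in data else np.arange(len(resid)),
            "residual": resid,
        }
    )
    lag1 = {}
    for region, g in series.groupby("region_id"):
        r = g.sort_values("date")["residual"].to_numpy()
        if len(r) >= 3 and np.std(r[:-1]) > 0 and np.std(r[1:]) > 0:
            lag1[region] = float(np.corrcoef(r[:-1], r[1:])[0, 1])
        else:
            lag1[region] = float("nan")
    if np.ptp(resid) > 0:
        sw_stat, sw_p = stats.shapiro(resid)
    else:
        sw_stat, sw_p = float("nan"), float("nan")
    return {
        "residuals": series,
        "lag1_autocorrelation": lag1,
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
        "sum_squared": float(np.sum(resid**2)),
    }
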