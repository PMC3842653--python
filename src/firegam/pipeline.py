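"""End-to-end orchestration: data in, fitted model + selection trace +
effects table + diagnostics out, every stage written as CSV/JSON with a run
manifest (package/library versions, seed, config hash).

Deterministic given the configuration and seed: rerunning with the same
config reproduces numerically identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .effects import build_effects_table, export_surfaces, residual_diagnostics
from .exposure import half_gaussian_kernel, merge_pm_classes
from .gam import ModelSpec, SmoothTerm, TensorTerm, fit_binomial_gam, fit_summaries, term_pvalues
from .io import (
    read_counts, read_covariates, read_demographics,
    write_counts, write_covariates, write_demographics,
)
from .selection import backward_eliminate
from .synth import aggregate_to_county, build_model_frame, simulate_dataset

log = logging.getLogger("firegam")

__all__ = ["run_pipeline", "spec_to_dict", "spec_from_dict", "assemble_dataset"]


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "response": list(spec.response),
        "linear_terms": list(spec.linear_terms),
        "indicator_terms": list(spec.indicator_terms),
        "smooth_terms": [{"covariate": s.covariate, "basis_size": s.basis_size} for s in spec.smooth_terms],
        "tensor_terms": [
            {"covariate_a": t.covariate_a, "covariate_b": t.covariate_b, "size_a": t.size_a, "size_b": t.size_b}
            for t in spec.tensor_terms
        ],
    }


def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        response=tuple(d.get("response", ("visits", "population"))),
        linear_terms=tuple(d.get("linear_terms", ())),
        indicator_terms=tuple(d.get("indicator_terms", ())),
        smooth_terms=tuple(SmoothTerm(**s) for s in d.get("smooth_terms", ())),
        tensor_terms=tuple(TensorTerm(**t) for t in d.get("tensor_terms", ())),
    )


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def assemble_dataset(config: RunConfig) -> dict:
    """Stage 1-2: acquire tables (synthetic or CSV) and build the model-ready
    frame with the lag-kernel fire-PM exposure at the requested aggregation."""
    kernel = half_gaussian_kernel(config.kernel_sd, config.kernel_lags)
    if config.synthetic is not None:
        ds = simulate_dataset(config.synthetic)
        if config.level == "county" and len(config.synthetic.regions) > 1:
            ds = aggregate_to_county(ds, kernel)
    else:
        counts = read_counts(config.inputs["counts"])
        covariates = read_covariates(config.inputs["covariates"])
        demographics = read_demographics(config.inputs["demographics"])
        pops = counts.groupby("region_id")["population"].first().astype(int).to_dict()
        frame = build_model_frame(covariates, demographics, pops, kernel)
        frame = frame.merge(counts[["region_id", "date", "visits"]], on=["region_id", "date"])
        frame["visits"] = frame["visits"].astype(float)
        ds = {"counts": counts, "covariates": covariates, "demographics": demographics,
              "model_frame": frame, "populations": pops}

    # concurvity screen on the pooled fire-PM series
    merged, report = merge_pm_classes(
        ds["covariates"]["fire_pm25"].to_numpy(), ds["covariates"]["fire_pm10"].to_numpy()
    )
    ds["pm_merge_report"] = report
    return ds


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/ingest -> exposure -> fit -> select -> report end-to-end.

    Returns a bundle dict and writes all stage outputs under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: level=%s seed=%d out=%s", config.level, config.seed, out)

    ds = assemble_dataset(config)
    frame = ds["model_frame"]
    write_counts(ds["counts"], out / "counts.csv")
    write_covariates(ds["covariates"], out / "covariates.csv")
    write_demographics(ds["demographics"], out / "demographics.csv")
    frame_out = frame.copy()
    frame_out["date"] = pd.DatetimeIndex(frame_out["date"]).strftime("%Y-%m-%d")
    frame_out.to_csv(out / "model_frame.csv", index=False)

    spec = config.spec()
    if config.select:
        log.info("backward elimination at alpha=%.3g", config.alpha)
        trace = backward_eliminate(spec, frame, alpha=config.alpha)
        if trace.failed:
            raise RuntimeError(f"selection failed: {trace.failure_message}")
        fitted = trace.final_fit
        final_spec = trace.final_spec
        pd.DataFrame(
            [{"step": s.step, "action": s.action, "term": s.term,
              "p_value": s.p_value, "deviance": s.deviance} for s in trace.steps]
        ).to_csv(out / "selection_trace.csv", index=False)
    else:
        trace = None
        fitted = fit_binomial_gam(spec, frame)
        final_spec = spec

    # coefficient table on both scales
    rows = [{"term": "intercept", "estimate": fitted.coef[0], "se": fitted.intercept_se,
             "odds_ratio": float(np.exp(fitted.coef[0]))}]
    pvals = term_pvalues(fitted)
    for name, blk in fitted.design.blocks.items():
        if blk.kind in ("linear", "indicator"):
            est = float(fitted.coef[blk.sl][0])
            rows.append({"term": name, "estimate": est, "se": fitted.se(name),
                         "odds_ratio": float(np.exp(est)), "p_value": pvals[name]})
        else:
            rows.append({"term": name, "edf": fitted.edf_by_term[name], "p_value": pvals[name]})
    pd.DataFrame(rows).to_csv(out / "coefficients.csv", index=False)

    ranges = {
        t: (float(frame[t].min()), float(frame[t].max()))
        for t in final_spec.linear_terms
    }
    effects = build_effects_table(fitted, ranges)
    effects.to_csv(out / "effects_table.csv", index=False)

    surfaces = export_surfaces(fitted)
    for name, grid in surfaces.items():
        safe = name.replace("(", "_").replace(")", "").replace(",", "_")
        grid.to_csv(out / f"surface_{safe}.csv", index=False)

    diag = residual_diagnostics(fitted, frame)
    diag["residuals"].assign(date=lambda d: pd.DatetimeIndex(d["date"]).strftime("%Y-%m-%d")).to_csv(
        out / "residuals.csv", index=False
    )

    summ = fit_summaries(fitted)
    summary = {
        "deviance": summ["deviance"],
        "null_deviance": summ["null_deviance"],
        "deviance_explained": summ["deviance_explained"],
        "r2_adj": summ["r2_adj"],
        "edf_total": summ["edf_total"],
        "gcv": summ["gcv"],
        "converged": fitted.converged,
        "final_terms": final_spec.term_names(),
        "lag1_autocorrelation": diag["lag1_autocorrelation"],
        "shapiro_p": diag["shapiro_p"],
        "pm_merge": {"merged": ds["pm_merge_report"].merged,
                     "correlation": ds["pm_merge_report"].correlation,
                     "degenerate": ds["pm_merge_report"].degenerate},
    }
    (out / "fit_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "final_spec.json").write_text(json.dumps(spec_to_dict(final_spec), indent=2))

    manifest = {
        "firegam": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "level": config.level,
        "alpha": config.alpha,
        "kernel": {"sd": config.kernel_sd, "max_lag": config.kernel_lags},
        "config_sha256": _config_hash(config),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline done: deviance explained %.3f, %d terms",
             summary["deviance_explained"], len(summary["final_terms"]))

    return {
        "dataset": ds,
        "fitted": fitted,
        "selection": trace,
        "effects": effects,
        "surfaces": surfaces,
        "diagnostics": diag,
        "summary": summary,
        "manifest": manifest,
    }
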