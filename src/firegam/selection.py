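"""Term selection: the linear-vs-nonlinear "plot and confidence bound" rule
and backward elimination at a nominal significance threshold.

A smooth is declared linear when some straight line fits entirely inside its
pointwise 95% confidence band — a small linear-program feasibility problem in
the line's intercept and slope.  Backward elimination then repeatedly (i)
fits, (ii) demotes any smooth whose band admits a straight line to a plain
linear term, and (iii) removes the single least-significant term whose
p-value exceeds alpha, until every remaining term is significant.  Ties are
broken lexicographically so the procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gam import (
    FittedModel,
    ModelSpec,
    SmoothEstimate,
    fit_binomial_gam,
    smooth_confidence_bands,
    term_pvalues,
)

__all__ = ["linearity_decision", "backward_eliminate", "SelectionTrace", "SelectionStep"]


def linearity_decision(estimate: SmoothEstimate) -> str:
    """Return ``"linear"`` iff a straight line fits within the 95% band.

    Feasibility of ``lower(g) <= a + b*g <= upper(g)`` at every grid point is
    checked as a linear program in (a, b).  Zero-width bands reduce to an
    exact containment test, which the LP handles as equality constraints.
    """
    g = np.asarray(estimate.grid, dtype=float)
    lo = np.asarray(estimate.lower, dtype=float)
    hi = np.asarray(estimate.upper, dtype=float)
    if len(g) < 2:
        raise ValueError("need a grid of at least 2 points")
    # a + b*g <= hi  and  -(a + b*g) <= -lo
    A = np.vstack([np.column_stack([np.ones_like(g), g]), -np.column_stack([np.ones_like(g), g])])
    ub = np.concatenate([hi, -lo])
    res = linprog(c=[0.0, 0.0], A_ub=A, b_ub=ub, bounds=[(None, None), (None, None)], method="highs")
    return "linear" if res.status == 0 else "nonlinear"


@dataclass
class SelectionStep:
    step: int
    action: str          # "demote" | "remove"
    term: str
    p_value: float | None
    deviance: float


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)
    final_spec: ModelSpec = None
    final_fit: FittedModel = None
    failed: bool = False
    failure_message: str = ""

    @property
    def removed(self) -> list:
        return [s.term for s in self.steps if s.action == "remove"]

    @property
    def demoted(self) -> list:
        return [s.term for s in self.steps if s.action == "demote"]


def backward_eliminate(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    band_grid_points: int = 50,
    **fit_kwargs,
) -> SelectionTrace:
    """Backward elimination with smooth demotion.

    Each round: fit; demote (one at a time, lexicographic order) any
    univariate smooth whose confidence band admits a straight line; then drop
    the single term with the largest p-value above ``alpha`` (Wald chi-square
    for linear/indicator terms, the approximate chi-square test for smooths
    and tensors).  The intercept is never removed.  Tensor terms are tested
    as a unit and are never demoted.  A refit failure returns the trace with
    its failure flag set at the offending step.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    trace = SelectionTrace()
    step = 0
    current = spec
    while True:
        try:
            fit = fit_binomial_gam(current, data, **fit_kwargs)
        except Exception as exc:  # refit failure is reported, not raised
            trace.failed = True
            trace.failure_message = f"refit failed: {exc}"
            trace.final_spec = current
            return trace

        # (ii) demotion pass: first feasible smooth (name order), then refit
        demoted = False
        for s in sorted(current.smooth_terms, key=lambda s: s.name):
            est = smooth_confidence_bands(fit, s.name, n_grid=band_grid_points)
            if linearity_decision(est) == "linear":
                step += 1
                trace.steps.append(SelectionStep(step, "demote", s.name, None, fit.deviance))
                current = current.demote(s.name)
                demoted = True
                break
        if demoted:
            continue

        # (iii) removal pass: largest p above alpha, ties lexicographic
        pvals = term_pvalues(fit)
        candidates = sorted(pvals.items(), key=lambda kv: (-kv[1], kv[0]))
        if candidates and candidates[0][1] > alpha:
            term, p = candidates[0]
            step += 1
            trace.steps.append(SelectionStep(step, "remove", term, float(p), fit.deviance))
            current = current.without(term)
            if not current.term_names():
                # intercept-only model remains; fit it and stop
                fit = fit_binomial_gam(current, data, **fit_kwargs)
                break
            continue
        break

    trace.final_spec = current
    trace.final_fit = fit
    return trace
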