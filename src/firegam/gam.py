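"""Penalized binomial-logistic generalized additive model, from scratch.

Counts y_ij (ED visits) from region j on day i are modeled as
Binomial(n_ij, p_ij) with

    logit(p_ij) = beta_0 + sum_k beta_k x_ijk + sum_m f_m(x_ijm)

where the f_m are natural cubic spline smooths (optionally bivariate
tensor-product smooths) with integrated-squared-second-derivative penalties.
Fitting is penalized iteratively reweighted least squares (PIRLS); the
smoothing parameter of each penalty minimizes the deviance-based generalized
cross-validation score

    GCV(lambda) = n * D(lambda) / (n - edf(lambda))^2 .

Smooths are centered (sum-to-zero over the observed covariate values) so the
intercept carries the level; each smooth's effective degrees of freedom (edf)
is the trace of the corresponding block of the influence matrix.  With no
smooth terms the fit reduces exactly to an unpenalized logistic GLM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .basis import NaturalCubicBasis, natural_cubic_basis, tensor_product_basis

__all__ = [
    "SmoothTerm",
    "TensorTerm",
    "ModelSpec",
    "FittedModel",
    "SmoothEstimate",
    "fit_binomial_gam",
    "gcv_score",
    "predict",
    "smooth_confidence_bands",
    "smooth_term_test",
    "smooth_term_pvalue",
    "term_pvalues",
    "fit_summaries",
    "deviance_residuals",
    "SeparationError",
    "NotConvergedWarning",
]


class SeparationError(RuntimeError):
    """Unbounded coefficient estimates (quasi-complete separation)."""


class NotConvergedWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class SmoothTerm:
    covariate: str
    basis_size: int = 10

    def __post_init__(self):
        if self.basis_size < 3:
            raise ValueError("smooth basis_size must be >= 3")

    @property
    def name(self) -> str:
        return f"s({self.covariate})"


@dataclass(frozen=True)
class TensorTerm:
    covariate_a: str
    covariate_b: str
    size_a: int = 5
    size_b: int = 5

    def __post_init__(self):
        if self.covariate_a == self.covariate_b:
            raise ValueError("tensor margins must differ")
        if min(self.size_a, self.size_b) < 3:
            raise ValueError("tensor marginal basis sizes must be >= 3")

    @property
    def name(self) -> str:
        return f"te({self.covariate_a},{self.covariate_b})"


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of the linear, indicator, smooth and tensor terms."""

    response: tuple[str, str] = ("visits", "population")
    linear_terms: tuple[str, ...] = ()
    indicator_terms: tuple[str, ...] = ()
    smooth_terms: tuple[SmoothTerm, ...] = ()
    tensor_terms: tuple[TensorTerm, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "linear_terms", tuple(self.linear_terms))
        object.__setattr__(self, "indicator_terms", tuple(self.indicator_terms))
        object.__setattr__(
            self,
            "smooth_terms",
            tuple(s if isinstance(s, SmoothTerm) else SmoothTerm(*s) for s in self.smooth_terms),
        )
        object.__setattr__(
            self,
            "tensor_terms",
            tuple(t if isinstance(t, TensorTerm) else TensorTerm(*t) for t in self.tensor_terms),
        )
        smooth_cov = {s.covariate for s in self.smooth_terms}
        overlap = smooth_cov & set(self.linear_terms)
        if overlap:
            raise ValueError(f"covariates in both linear and smooth roles: {sorted(overlap)}")
        names = self.term_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate term names in model spec")

    def term_names(self) -> list[str]:
        return (
            list(self.linear_terms)
            + list(self.indicator_terms)
            + [s.name for s in self.smooth_terms]
            + [t.name for t in self.tensor_terms]
        )

    def without(self, term: str) -> "ModelSpec":
        """Spec with the named term removed."""
        return replace(
            self,
            linear_terms=tuple(t for t in self.linear_terms if t != term),
            indicator_terms=tuple(t for t in self.indicator_terms if t != term),
            smooth_terms=tuple(s for s in self.smooth_terms if s.name != term),
            tensor_terms=tuple(t for t in self.tensor_terms if t.name != term),
        )

    def demote(self, smooth_name: str) -> "ModelSpec":
        """Reclassify a univariate smooth as a plain linear term."""
        match = [s for s in self.smooth_terms if s.name == smooth_name]
        if not match:
            raise KeyError(f"no smooth term named {smooth_name!r}")
        return replace(
            self,
            linear_terms=self.linear_terms + (match[0].covariate,),
            smooth_terms=tuple(s for s in self.smooth_terms if s.name != smooth_name),
        )


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _TermBlock:
    name: str
    kind: str                      # linear | indicator | smooth | tensor
    sl: slice
    basis: object = None           # NaturalCubicBasis or TensorProductBasis
    center: np.ndarray = None      # column means removed (smooth/tensor)


@dataclass
class _PenaltyBlock:
    term: str
    sl: slice
    matrix: np.ndarray             # block-size PSD penalty


class Design:
    """Model matrix plus everything needed to rebuild it on new data."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        cols = [np.ones((len(data), 1))]
        self.blocks: dict[str, _TermBlock] = {}
        self.penalties: list[_PenaltyBlock] = []
        pos = 1

        def col(name):
            if name not in data.columns:
                raise KeyError(f"unknown covariate {name!r}")
            return data[name].to_numpy(dtype=float)

        for t in spec.linear_terms:
            cols.append(col(t)[:, None])
            self.blocks[t] = _TermBlock(t, "linear", slice(pos, pos + 1))
            pos += 1
        for t in spec.indicator_terms:
            v = col(t)
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError(f"indicator term {t!r} must be 0/1 coded")
            cols.append(v[:, None])
            self.blocks[t] = _TermBlock(t, "indicator", slice(pos, pos + 1))
            pos += 1
        for s in spec.smooth_terms:
            x = col(s.covariate)
            basis = natural_cubic_basis(x, s.basis_size, covariate=s.covariate)
            B = basis.evaluate(x)[:, 1:]          # drop the constant column
            center = B.mean(axis=0)
            cols.append(B - center)
            sl = slice(pos, pos + B.shape[1])
            self.blocks[s.name] = _TermBlock(s.name, "smooth", sl, basis, center)
            self.penalties.append(_PenaltyBlock(s.name, sl, basis.penalty[1:, 1:]))
            pos += B.shape[1]
        for t in spec.tensor_terms:
            u, v = col(t.covariate_a), col(t.covariate_b)
            ba = natural_cubic_basis(u, t.size_a, covariate=t.covariate_a)
            bb = natural_cubic_basis(v, t.size_b, covariate=t.covariate_b)
            tp = tensor_product_basis(ba, bb)
            T = tp.evaluate(u, v)[:, 1:]          # drop the constant*constant column
            center = T.mean(axis=0)
            cols.append(T - center)
            sl = slice(pos, pos + T.shape[1])
            self.blocks[t.name] = _TermBlock(t.name, "tensor", sl, tp, center)
            for P in tp.penalties():
                self.penalties.append(_PenaltyBlock(t.name, sl, P[1:, 1:]))
            pos += T.shape[1]

        self.X = np.hstack(cols)
        self.n_coef = pos
        if np.linalg.matrix_rank(self.X) < self.n_coef:
            raise ValueError("design matrix is rank deficient after constraints")

    def build(self, data: pd.DataFrame) -> np.ndarray:
        """Model matrix for new data using the stored knots and centerings."""
        X = np.ones((len(data), self.n_coef))

        def col(name):
            if name not in data.columns:
                raise KeyError(f"unknown covariate {name!r}")
            return data[name].to_numpy(dtype=float)

        for blk in self.blocks.values():
            if blk.kind in ("linear", "indicator"):
                X[:, blk.sl] = col(blk.name)[:, None]
            elif blk.kind == "smooth":
                x = col(blk.basis.covariate)
                X[:, blk.sl] = blk.basis.evaluate(x)[:, 1:] - blk.center
            else:
                tp = blk.basis
                X[:, blk.sl] = (
                    tp.evaluate(col(tp.margin_a.covariate), col(tp.margin_b.covariate))[:, 1:]
                    - blk.center
                )
        return X

    def full_penalties(self) -> list[np.ndarray]:
        out = []
        for pb in self.penalties:
            S = np.zeros((self.n_coef, self.n_coef))
            S[pb.sl, pb.sl] = pb.matrix
            out.append(S)
        return out


# ---------------------------------------------------------------------------
# fitting


def _binom_deviance(y, n, p):
    mu = n * p
    d = special.xlogy(y, y) - special.xlogy(y, mu) + special.xlogy(n - y, n - y) - special.xlogy(
        n - y, n - mu
    )
    return 2.0 * d


def _pirls(X, y, n, S, beta=None, tol=1e-8, max_iter=100):
    """Penalized IRLS for the binomial-logit likelihood.

    Returns (beta, eta, w, XtWX, deviance, converged, n_iter).  Raises
    SeparationError when the linear predictor diverges.
    """
    if beta is None:
        p = (y + 0.5) / (n + 1.0)
        eta = special.logit(p)
    else:
        eta = X @ beta
    p = special.expit(eta)
    dev = _binom_deviance(y, n, np.clip(p, 1e-12, 1 - 1e-12)).sum()
    converged = False
    w = XtWX = None
    for it in range(1, max_iter + 1):
        p = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
        w = np.maximum(n * p * (1 - p), 1e-12)
        z = eta + (y - n * p) / w
        XtW = X.T * w
        XtWX = XtW @ X
        try:
            beta = np.linalg.solve(XtWX + S, XtW @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtWX + S, XtW @ z, rcond=None)[0]
        eta = X @ beta
        if np.max(np.abs(eta)) > 60.0 or np.max(np.abs(beta)) > 1e6:
            raise SeparationError(
                "linear predictor diverged; data appear separated (unbounded coefficients)"
            )
        new_dev = _binom_deviance(y, n, np.clip(special.expit(eta), 1e-12, 1 - 1e-12)).sum()
        if abs(new_dev - dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    # |eta| this large means fitted probabilities at the floating-point
    # boundary: the MLE is diverging (quasi-complete separation)
    if np.max(np.abs(eta)) > 30.0:
        raise SeparationError(
            "fitted probabilities pinned at 0/1; data appear separated (unbounded coefficients)"
        )
    return beta, eta, w, XtWX, dev, converged, it


def gcv_score(deviance: float, n_obs: int, edf: float) -> float:
    """Deviance-based GCV: n * D / (n - edf)^2 (infinite when edf >= n)."""
    if edf >= n_obs:
        return np.inf
    return n_obs * deviance / (n_obs - edf) ** 2


@dataclass
class FittedModel:
    spec: ModelSpec
    design: Design
    coef: np.ndarray
    cov: np.ndarray                 # Bayesian (A + S)^-1; used for bands/Wald
    cov_freq: np.ndarray            # frequentist F (A + S)^-1
    lambdas: np.ndarray             # one per penalty block
    edf_by_term: dict
    edf_total: float
    deviance: float
    null_deviance: float
    gcv: float
    converged: bool
    n_iter: int
    y: np.ndarray
    trials: np.ndarray
    eta: np.ndarray
    fitted_p: np.ndarray

    @property
    def coefficients(self) -> dict:
        out = {"intercept": float(self.coef[0])}
        for name, blk in self.design.blocks.items():
            if blk.kind in ("linear", "indicator"):
                out[name] = float(self.coef[blk.sl][0])
        return out

    def se(self, term: str) -> float:
        blk = self.design.blocks[term]
        if blk.kind not in ("linear", "indicator"):
            raise ValueError("se() applies to linear/indicator terms")
        return float(np.sqrt(self.cov[blk.sl, blk.sl][0, 0]))

    @property
    def intercept_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))


def _finalize(design, beta, eta, w, XtWX, dev, lam, null_dev, converged, n_iter, y, n):
    penalties = getattr(design, "_scaled_penalties", None) or design.full_penalties()
    S = sum(l * P for l, P in zip(lam, penalties)) if len(lam) else 0.0
    A = XtWX
    H = np.linalg.inv(A + S) if np.ndim(S) else np.linalg.inv(A)
    F = H @ A
    edf_diag = np.diag(F)
    edf_by_term = {"intercept": float(edf_diag[0])}
    for name, blk in design.blocks.items():
        edf_by_term[name] = float(edf_diag[blk.sl].sum())
    edf_total = float(edf_diag.sum())
    return FittedModel(
        spec=design.spec,
        design=design,
        coef=beta,
        cov=H,
        cov_freq=F @ H,
        lambdas=np.asarray(lam, dtype=float),
        edf_by_term=edf_by_term,
        edf_total=edf_total,
        deviance=float(dev),
        null_deviance=float(null_dev),
        gcv=gcv_score(dev, len(y), edf_total),
        converged=converged,
        n_iter=n_iter,
        y=y,
        trials=n,
        eta=eta,
        fitted_p=special.expit(eta),
    )


def fit_binomial_gam(
    spec: ModelSpec,
    data: pd.DataFrame,
    lambdas="gcv",
    log10_grid=(-6.0, 6.0, 30),
    sweeps: int = 2,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FittedModel:
    """Fit the penalized binomial-logit GAM.

    Parameters
    ----------
    spec, data
        Model declaration and the long-format region-day table.  The response
        columns are ``spec.response`` (successes, trials).
    lambdas
        ``"gcv"`` (default) selects each penalty's smoothing parameter by
        coordinate-wise grid search on log10(lambda) followed by golden-section
        refinement; a sequence fixes the smoothing parameters; with no
        penalized terms the fit is an ordinary logistic GLM.
    """
    y = data[spec.response[0]].to_numpy(dtype=float)
    n = data[spec.response[1]].to_numpy(dtype=float)
    if np.any(n <= 0):
        raise ValueError("trials (population) must be positive")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= successes <= trials")

    design = Design(spec, data)
    X = design.X
    penalties = design.full_penalties()
    # rescale each penalty to the information scale of its block so the
    # log10(lambda) grid is scale-free in the covariate units
    p0 = (y + 0.5) / (n + 1.0)
    w0 = n * p0 * (1 - p0)
    A0 = (X.T * w0) @ X
    for i, pb in enumerate(design.penalties):
        a_norm = np.linalg.norm(A0[pb.sl, pb.sl])
        s_norm = np.linalg.norm(pb.matrix)
        if s_norm > 0:
            penalties[i] = penalties[i] * (a_norm / s_norm)
    design._scaled_penalties = penalties
    n_pen = len(penalties)

    # null (intercept-only) deviance
    _, _, _, _, null_dev, _, _ = _pirls(np.ones((len(y), 1)), y, n, 0.0, tol=tol)

    if n_pen == 0:
        beta, eta, w, XtWX, dev, conv, it = _pirls(X, y, n, 0.0, tol=tol, max_iter=max_iter)
        return _finalize(design, beta, eta, w, XtWX, dev, [], null_dev, conv, it, y, n)

    if not (isinstance(lambdas, str) and lambdas == "gcv"):
        lam = np.asarray(lambdas, dtype=float)
        if lam.shape != (n_pen,):
            raise ValueError(f"expected {n_pen} smoothing parameters")
        S = sum(l * P for l, P in zip(lam, penalties))
        beta, eta, w, XtWX, dev, conv, it = _pirls(X, y, n, S, tol=tol, max_iter=max_iter)
        return _finalize(design, beta, eta, w, XtWX, dev, lam, null_dev, conv, it, y, n)

    # --- GCV optimization, coordinate-wise with warm starts -----------------
    state = {"beta": None}

    def evaluate(lam):
        S = sum(l * P for l, P in zip(lam, penalties))
        try:
            beta, eta, w, XtWX, dev, conv, it = _pirls(
                X, y, n, S, beta=state["beta"], tol=tol, max_iter=max_iter
            )
        except SeparationError:
            return np.inf, None
        state["beta"] = beta
        H = np.linalg.inv(XtWX + S)
        edf = float(np.trace(H @ XtWX))
        return gcv_score(dev, len(y), edf), (beta, eta, w, XtWX, dev, conv, it)

    grid = np.logspace(log10_grid[0], log10_grid[1], int(log10_grid[2]))
    lam = np.full(n_pen, 1.0)
    best_idx = np.full(n_pen, len(grid) // 2)
    for _ in range(sweeps):
        for j in range(n_pen):
            scores = []
            for gi, g in enumerate(grid):
                trial = lam.copy()
                trial[j] = g
                scores.append(evaluate(trial)[0])
            best_idx[j] = int(np.argmin(scores))
            lam[j] = grid[best_idx[j]]

    # golden-section refinement of each coordinate within its grid bracket
    for j in range(n_pen):
        bi = best_idx[j]
        if 0 < bi < len(grid) - 1:
            lo, hi = np.log10(grid[bi - 1]), np.log10(grid[bi + 1])

            def f(loglam, j=j):
                trial = lam.copy()
                trial[j] = 10.0**loglam
                return evaluate(trial)[0]

            res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                           options={"maxiter": 20, "xatol": 1e-3})
            if res.fun <= f(np.log10(lam[j])):
                lam[j] = 10.0**res.x

    score, payload = evaluate(lam)
    beta, eta, w, XtWX, dev, conv, it = payload
    return _finalize(design, beta, eta, w, XtWX, dev, lam, null_dev, conv, it, y, n)


# ---------------------------------------------------------------------------
# inference and summaries


def predict(fitted: FittedModel, newdata: pd.DataFrame) -> dict:
    """Probabilities with delta-method standard errors on both scales.

    Returns a dict with ``eta``, ``se_eta`` (link scale), ``prob``,
    ``se_prob`` (= p(1-p) se_eta), and, when the trials column is present in
    ``newdata``, ``expected`` = n * p with its standard error.
    """
    Xn = fitted.design.build(newdata)
    eta = Xn @ fitted.coef
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", Xn, fitted.cov, Xn))
    p = special.expit(eta)
    se_p = p * (1 - p) * se_eta
    out = {"eta": eta, "se_eta": se_eta, "prob": p, "se_prob": se_p}
    trials_col = fitted.spec.response[1]
    if trials_col in newdata.columns:
        n = newdata[trials_col].to_numpy(dtype=float)
        out["expected"] = n * p
        out["se_expected"] = n * se_p
    return out


@dataclass
class SmoothEstimate:
    term: str
    grid: np.ndarray
    fit: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def smooth_confidence_bands(
    fitted: FittedModel, term: str, grid: np.ndarray | None = None, n_grid: int = 100
) -> SmoothEstimate:
    """Centered smooth estimate with pointwise 95% bands (+-1.96 se)."""
    if term not in fitted.design.blocks or fitted.design.blocks[term].kind != "smooth":
        raise KeyError(f"no univariate smooth term named {term!r}")
    blk = fitted.design.blocks[term]
    knots = blk.basis.knots
    if grid is None:
        grid = np.linspace(knots[0], knots[-1], n_grid)
    grid = np.asarray(grid, dtype=float)
    B = blk.basis.evaluate(grid)[:, 1:] - blk.center
    b = fitted.coef[blk.sl]
    V = fitted.cov[blk.sl, blk.sl]
    f = B @ b
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
    return SmoothEstimate(term, grid, f, se, f - 1.96 * se, f + 1.96 * se)


def smooth_term_test(fitted: FittedModel, term: str):
    """Approximate chi-square Wald test for a smooth or tensor term.

    The statistic is b' V^- b with the pseudo-inverse of the term's coefficient
    covariance block truncated at rank = rounded edf, referred to chi-square
    with that many degrees of freedom.
    """
    blk = fitted.design.blocks.get(term)
    if blk is None or blk.kind not in ("smooth", "tensor"):
        raise KeyError(f"no smooth/tensor term named {term!r}")
    b = fitted.coef[blk.sl]
    V = fitted.cov[blk.sl, blk.sl]
    B = fitted.design.X[:, blk.sl]
    # rank-truncated pseudo-inverse Wald test on the fitted function values
    # f_hat = B b with Cov(f_hat) = B V B'; computed in coefficient space via
    # the shared nonzero spectrum of V^{1/2} B'B V^{1/2}
    e, E = np.linalg.eigh(0.5 * (V + V.T))
    L = E * np.sqrt(np.clip(e, 0.0, None))
    G = B.T @ B
    K = L.T @ G @ L
    d, Q = np.linalg.eigh(0.5 * (K + K.T))
    order = np.argsort(d)[::-1]
    d, Q = d[order], Q[:, order]
    usable = int(np.sum(d > max(d[0], 0.0) * 1e-10))
    if usable == 0:
        raise FloatingPointError(f"degenerate covariance for term {term!r}")
    rank = int(np.clip(round(fitted.edf_by_term[term]), 1, usable))
    proj = Q[:, :rank].T @ (L.T @ (G @ b))
    stat = float(np.sum(proj**2 / d[:rank] ** 2))
    p = float(stats.chi2.sf(stat, rank))
    return stat, rank, p


def smooth_term_pvalue(fitted: FittedModel, term: str) -> float:
    return smooth_term_test(fitted, term)[2]


def term_pvalues(fitted: FittedModel) -> dict:
    """Per-term p-values: Wald chi-square(1) for linear/indicator terms,
    the approximate chi-square test for smooth/tensor terms."""
    out = {}
    for name, blk in fitted.design.blocks.items():
        if blk.kind in ("linear", "indicator"):
            est = fitted.coef[blk.sl][0]
            se = np.sqrt(fitted.cov[blk.sl, blk.sl][0, 0])
            out[name] = float(stats.chi2.sf((est / se) ** 2, 1))
        else:
            out[name] = smooth_term_pvalue(fitted, name)
    return out


def deviance_residuals(fitted: FittedModel) -> np.ndarray:
    """Signed per-observation deviance residuals; their squares sum to D."""
    d = _binom_deviance(fitted.y, fitted.trials, np.clip(fitted.fitted_p, 1e-12, 1 - 1e-12))
    return np.sign(fitted.y - fitted.trials * fitted.fitted_p) * np.sqrt(np.maximum(d, 0.0))


def fit_summaries(fitted: FittedModel) -> dict:
    """Deviance explained, adjusted R^2 and the deviance residual vector."""
    n = len(fitted.y)
    if fitted.null_deviance > 0:
        dev_expl = 1.0 - fitted.deviance / fitted.null_deviance
        r2_adj = 1.0 - (fitted.deviance / max(n - fitted.edf_total, 1e-12)) / (
            fitted.null_deviance / (n - 1)
        )
    else:
        dev_expl, r2_adj = 0.0, 0.0
    return {
        "deviance": fitted.deviance,
        "null_deviance": fitted.null_deviance,
        "deviance_explained": dev_expl,
        "r2_adj": r2_adj,
        "edf_total": fitted.edf_total,
        "gcv": fitted.gcv,
        "deviance_residuals": deviance_residuals(fitted),
    }
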