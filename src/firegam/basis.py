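"""Natural cubic spline bases with curvature penalties, and tensor products.

The univariate basis is the truncated-power natural cubic spline basis with
knots at quantiles of the observed (unique) covariate values: N1(x) = 1,
N2(x) = x and, for k = 1..K-2,

    N_{k+2}(x) = d_k(x) - d_{K-1}(x),
    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k),

which is linear beyond the boundary knots.  The roughness penalty is the Gram
matrix of integrated squared second derivatives, Omega_ij = int N_i'' N_j'' dx.
Because natural-spline second derivatives are piecewise linear between knots,
per-interval Simpson quadrature evaluates the integral exactly; the constant
and linear basis functions span the penalty's null space.

Tensor-product smooths take the row-wise product of two marginal bases and
carry one penalty per margin (Omega_a (x) I and I (x) Omega_b), so a surface
that is additive in one margin incurs no penalty from the other margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NaturalCubicBasis", "TensorProductBasis", "natural_cubic_basis", "tensor_product_basis"]


@dataclass(frozen=True)
class NaturalCubicBasis:
    covariate: str
    knots: np.ndarray          # strictly increasing, length K
    penalty: np.ndarray = field(default=None)  # K x K, PSD, null space {1, x}

    @property
    def size(self) -> int:
        return len(self.knots)

    def _d(self, x: np.ndarray, k: int) -> np.ndarray:
        xi = self.knots
        K = len(xi)
        return (np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[K - 1], 0, None) ** 3) / (
            xi[K - 1] - xi[k]
        )

    def _d2(self, x: np.ndarray, k: int) -> np.ndarray:
        # second derivative of _d: piecewise linear
        xi = self.knots
        K = len(xi)
        return 6.0 * (np.clip(x - xi[k], 0, None) - np.clip(x - xi[K - 1], 0, None)) / (
            xi[K - 1] - xi[k]
        )

    def evaluate(self, x) -> np.ndarray:
        """Basis matrix at arbitrary points, shape (len(x), K)."""
        x = np.asarray(x, dtype=float)
        K = len(self.knots)
        N = np.empty((len(x), K))
        N[:, 0] = 1.0
        N[:, 1] = x
        dKm2 = self._d(x, K - 2)
        for k in range(K - 2):
            N[:, k + 2] = self._d(x, k) - dKm2
        return N

    def second_derivative(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        K = len(self.knots)
        D = np.zeros((len(x), K))
        d2Km2 = self._d2(x, K - 2)
        for k in range(K - 2):
            D[:, k + 2] = self._d2(x, k) - d2Km2
        return D


def _curvature_penalty(basis: NaturalCubicBasis) -> np.ndarray:
    """Exact Omega_ij = int N_i''(x) N_j''(x) dx over [xi_1, xi_K].

    Second derivatives are piecewise linear with breaks at the knots, so the
    integrand is piecewise quadratic and Simpson's rule on each knot interval
    is exact.
    """
    xi = basis.knots
    pts, wts = [], []
    for a, b in zip(xi[:-1], xi[1:]):
        h = b - a
        pts.extend([a, 0.5 * (a + b), b])
        wts.extend([h / 6.0, 4.0 * h / 6.0, h / 6.0])
    D = basis.second_derivative(np.array(pts))
    omega = D.T @ (np.asarray(wts)[:, None] * D)
    return 0.5 * (omega + omega.T)


def natural_cubic_basis(x, basis_size: int, covariate: str = "x") -> NaturalCubicBasis:
    """Build a natural cubic spline basis with knots at quantiles of x.

    Requires at least ``basis_size`` distinct covariate values (and
    ``basis_size >= 3`` for the curvature penalty to be meaningful).
    """
    if basis_size < 3:
        raise ValueError("basis_size must be >= 3")
    ux = np.unique(np.asarray(x, dtype=float))
    if len(ux) < basis_size:
        raise ValueError(
            f"need >= {basis_size} distinct values for covariate {covariate!r}, got {len(ux)}"
        )
    knots = np.quantile(ux, np.linspace(0, 1, basis_size))
    knots = np.unique(knots)
    if len(knots) < basis_size:
        raise ValueError(f"quantile knots collide for covariate {covariate!r}")
    b = NaturalCubicBasis(covariate=covariate, knots=knots)
    object.__setattr__(b, "penalty", _curvature_penalty(b))
    return b


@dataclass(frozen=True)
class TensorProductBasis:
    """Row-wise product of two marginal natural cubic bases."""

    margin_a: NaturalCubicBasis
    margin_b: NaturalCubicBasis

    def __post_init__(self):
        if self.margin_a.covariate == self.margin_b.covariate:
            raise ValueError("tensor margins must be different covariates")

    @property
    def size(self) -> int:
        return self.margin_a.size * self.margin_b.size

    def evaluate(self, u, v) -> np.ndarray:
        A = self.margin_a.evaluate(u)
        B = self.margin_b.evaluate(v)
        n, ka, kb = len(A), A.shape[1], B.shape[1]
        return (A[:, :, None] * B[:, None, :]).reshape(n, ka * kb)

    def penalties(self) -> list[np.ndarray]:
        """One PSD penalty per margin: [Omega_a (x) I_b, I_a (x) Omega_b]."""
        ka, kb = self.margin_a.size, self.margin_b.size
        return [
            np.kron(self.margin_a.penalty, np.eye(kb)),
            np.kron(np.eye(ka), self.margin_b.penalty),
        ]


def tensor_product_basis(a: NaturalCubicBasis, b: NaturalCubicBasis) -> TensorProductBasis:
    return TensorProductBasis(margin_a=a, margin_b=b)
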