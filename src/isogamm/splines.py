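"""Penalized B-spline (P-spline) bases and their mixed-model form.

A smooth term f(x) is represented as a rich cubic B-spline basis over the
angle domain combined with a difference penalty on adjacent coefficients.
The penalty ``S = D' D`` (order-``d`` differences) has a ``d``-dimensional
null space of degree-(d-1) polynomials; eigendecomposing S splits the smooth
into an unpenalized polynomial part (fixed effects) and penalized columns
whose coefficients behave as i.i.d. zero-mean random effects.  Smoothing then
amounts to estimating a variance component, which is what lets the smooth sit
inside a hierarchical Gaussian model and be updated by conjugate Gibbs steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


def bspline_knots(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    """Uniform interior knots on [lo, hi] with degree-replicated boundaries."""
    if not hi > lo:
        raise ValueError("degenerate domain")
    if n_basis < degree + 1:
        raise ValueError(f"n_basis must be >= degree + 1, got {n_basis} < {degree + 1}")
    n_interior = n_basis - degree - 1
    inner = np.linspace(lo, hi, n_interior + 2)
    return np.concatenate([np.full(degree, lo), inner, np.full(degree, hi)])


@dataclass
class BSplineBasis:
    """Evaluator for a B-spline basis on a closed domain (no extrapolation)."""

    domain: tuple[float, float]
    n_basis: int
    degree: int = 3
    knots: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        self.knots = bspline_knots(lo, hi, self.n_basis, self.degree)

    def __call__(self, x) -> np.ndarray:
        """Evaluate the basis: returns an (n, K) design matrix.

        Points outside the domain raise; the closed right endpoint is valid.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.domain
        if x.size and (x.min() < lo or x.max() > hi):
            raise ValueError(
                f"evaluation points outside domain [{lo}, {hi}]: "
                f"range [{x.min()}, {x.max()}]"
            )
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """Difference penalty S = D'D with D the order-``order`` difference operator.

    S is symmetric positive semidefinite with rank ``n_basis - order``; its
    null space is spanned by polynomial coefficient sequences of degree
    ``order - 1``.
    """
    if not 1 <= order < n_basis:
        raise ValueError(f"penalty order must satisfy 1 <= d < K, got d={order}, K={n_basis}")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass
class SmoothBasisSet:
    """A B-spline basis, its difference penalty, and the mixed-model split.

    ``design_null(x)`` gives the unpenalized polynomial columns X0 (one per
    null-space dimension, i.e. ``penalty_order`` of them); ``design_pen(x)``
    gives penalized columns Z scaled so that a unit ridge penalty on their
    coefficients reproduces the smoothing penalty: with S = U L U',
    Z(x) = B(x) U+ L+^(-1/2).
    """

    basis: BSplineBasis
    penalty_order: int = 2
    penalty: np.ndarray = field(init=False, repr=False)
    _U_null: np.ndarray = field(init=False, repr=False)
    _U_pen: np.ndarray = field(init=False, repr=False)
    _eig_pen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        K = self.basis.n_basis
        self.penalty = difference_penalty(K, self.penalty_order)
        eigval, eigvec = np.linalg.eigh(self.penalty)
        tol = eigval.max() * 1e-10
        if eigval.min() < -tol:
            raise ValueError("penalty eigendecomposition produced negative eigenvalues")
        null = eigval <= tol
        if null.sum() != self.penalty_order:
            raise ValueError(
                f"null-space dimension {null.sum()} != penalty order {self.penalty_order}"
            )
        self._U_null = eigvec[:, null]
        self._U_pen = eigvec[:, ~null]
        self._eig_pen = eigval[~null]

    @property
    def domain(self) -> tuple[float, float]:
        return self.basis.domain

    @property
    def n_basis(self) -> int:
        return self.basis.n_basis

    @property
    def n_null(self) -> int:
        return self.penalty_order

    @property
    def n_pen(self) -> int:
        return self.basis.n_basis - self.penalty_order

    def design_null(self, x) -> np.ndarray:
        """Unpenalized (polynomial) design columns X0(x), shape (n, d)."""
        return self.basis(x) @ self._U_null

    def design_pen(self, x) -> np.ndarray:
        """Penalized design columns Z(x), shape (n, K - d)."""
        return self.basis(x) @ (self._U_pen / np.sqrt(self._eig_pen))


def make_smooth(domain: tuple[float, float], n_basis: int = 10, degree: int = 3,
                penalty_order: int = 2) -> SmoothBasisSet:
    """Convenience constructor for the default cubic P-spline smooth."""
    return SmoothBasisSet(BSplineBasis(domain, n_basis, degree), penalty_order)


def penalized_lsq(B: np.ndarray, S: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Direct penalized least squares: solve (B'B + lam*S) b = B'y.

    Reference solver for checking the mixed-model reparameterization; a ridge
    of 1/tau^2 on the Z-coefficients is equivalent to lam = 1/tau^2 here.
    """
    K = B.shape[1]
    A = B.T @ B + lam * S
    # difference penalties leave a polynomial null space unpenalized; add a
    # vanishing ridge only to keep the solve well-posed when B is thin
    return np.linalg.solve(A + 1e-12 * np.eye(K), B.T @ y)
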