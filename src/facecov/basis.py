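"""Marginal B-spline bases, difference penalties and the symmetric-coefficient design.

The covariance surface is modelled as a symmetric tensor-product spline
``H(s, t) = sum_{k,l} theta_{kl} B_k(s) B_l(t)`` with ``Theta`` constrained to be
symmetric.  Working with the half-vectorization ``theta = vech(Theta)`` and the
duplication matrix ``G_c`` (``vec(Theta) = G_c theta``) turns the constrained
surface fit into an ordinary penalized regression with design rows
``[ (b(t2) kron b(t1))^T G_c , delta ]`` — one row per within-subject pair of
observations, plus an intercept-like column ``delta`` that carries the
measurement-error variance on diagonal ("nugget") pairs.

The roughness penalty is the row-wise second-difference penalty
``||Theta D||_F^2`` of bivariate P-splines; for a symmetric ``Theta`` row and
column penalties coincide, so a single term suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BSplineBasis",
    "PenaltyPack",
    "make_basis",
    "eval_basis",
    "difference_matrix",
    "duplication_matrix",
    "vech",
    "unvech",
    "penalty_matrices",
    "pair_indices",
    "subject_design",
]


@dataclass(frozen=True)
class BSplineBasis:
    """A clamped B-spline basis with equally spaced interior knots on [0, 1].

    ``n_basis`` (the paper-level ``c``) equals the number of interior knots
    plus the spline order (degree + 1).
    """

    n_basis: int
    degree: int
    knots: np.ndarray = field(repr=False)
    domain: tuple[float, float] = (0.0, 1.0)

    @property
    def n_interior_knots(self) -> int:
        return self.n_basis - self.degree - 1


def make_basis(n_basis: int, degree: int = 3, domain: tuple[float, float] = (0.0, 1.0)) -> BSplineBasis:
    """Build a clamped basis of ``n_basis`` functions of the given degree.

    Raises ``ValueError`` when ``n_basis < degree + 1`` (no valid knot vector).
    """
    if n_basis < degree + 1:
        raise ValueError(
            f"n_basis={n_basis} too small for degree {degree}; need at least {degree + 1}"
        )
    lo, hi = domain
    n_int = n_basis - degree - 1
    interior = lo + (hi - lo) * (np.arange(1, n_int + 1) / (n_int + 1))
    knots = np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])
    return BSplineBasis(n_basis=n_basis, degree=degree, knots=knots, domain=(lo, hi))


def eval_basis(basis: BSplineBasis, t: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at ``t``; returns an ``(len(t), c)`` matrix.

    Rows are non-negative and sum to one (partition of unity).  Points outside
    the domain raise a ``ValueError``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lo, hi = basis.domain
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"evaluation points outside the domain [{lo}, {hi}]")
    return BSpline.design_matrix(t, basis.knots, basis.degree, extrapolate=False).toarray()


def difference_matrix(n_basis: int, order: int = 2) -> np.ndarray:
    """Second-order difference operator ``D`` of shape ``(c, c - order)``.

    ``D.T @ theta`` computes the ``order``-th differences of a coefficient
    vector; the penalty built from it shrinks towards polynomials of degree
    ``order - 1``.
    """
    if n_basis < order + 1:
        raise ValueError(f"n_basis={n_basis} must exceed the difference order {order}")
    D = np.eye(n_basis)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D.T


def duplication_matrix(n_basis: int) -> np.ndarray:
    """0/1 operator ``G_c`` with ``G_c @ vech(Theta) = vec(Theta)`` for symmetric Theta.

    vech stacks the lower triangle column by column; vec is column-major.
    """
    c = n_basis
    G = np.zeros((c * c, c * (c + 1) // 2))
    half = {}
    k = 0
    for col in range(c):
        for row in range(col, c):
            half[(row, col)] = k
            k += 1
    for col in range(c):
        for row in range(c):
            r, s = (row, col) if row >= col else (col, row)
            G[row + c * col, half[(r, s)]] = 1.0
    return G


def vech(theta_mat: np.ndarray) -> np.ndarray:
    """Half-vectorization (lower triangle, column-major) of a square matrix."""
    c = theta_mat.shape[0]
    rows, cols = np.tril_indices(c)
    order = np.lexsort((rows, cols))  # column-major within the lower triangle
    return theta_mat[rows[order], cols[order]]


def unvech(theta: np.ndarray, n_basis: int) -> np.ndarray:
    """Inverse of :func:`vech` for a symmetric matrix of size ``n_basis``."""
    G = duplication_matrix(n_basis)
    return (G @ theta).reshape(n_basis, n_basis, order="F")


@dataclass(frozen=True)
class PenaltyPack:
    """Penalty operators for the symmetric tensor-product fit.

    ``P = G_c^T (I_c kron D D^T) G_c`` acts on ``vech(Theta)`` and reproduces
    ``||Theta D||_F^2``; ``Q`` pads ``P`` with a zero row/column so the error
    variance coordinate of ``alpha = (theta, sigma2)`` is unpenalized.
    """

    D: np.ndarray
    G: np.ndarray
    P: np.ndarray
    Q: np.ndarray


def penalty_matrices(basis: BSplineBasis) -> PenaltyPack:
    c = basis.n_basis
    D = difference_matrix(c)
    G = duplication_matrix(c)
    P = G.T @ np.kron(np.eye(c), D @ D.T) @ G
    P = 0.5 * (P + P.T)
    K = P.shape[0] + 1
    Q = np.zeros((K, K))
    Q[:-1, :-1] = P
    return PenaltyPack(D=D, G=G, P=P, Q=Q)


def psd_trim_theta(basis: BSplineBasis, theta: np.ndarray, grid_size: int = 100) -> np.ndarray:
    """Positive-semidefinite surrogate of a symmetric coefficient matrix.

    Evaluates the surface on a midpoint grid, trims negative eigenvalues of
    the grid covariance, and projects back onto the tensor-spline
    coefficients by least squares (``Theta+ = M C+ M'`` with
    ``M = (B'B)^{-1} B'``), which preserves positive semidefiniteness of the
    implied kernel.
    """
    g = grid_size
    grid = (np.arange(g) + 0.5) / g
    B = eval_basis(basis, grid)
    Cg = B @ theta @ B.T
    vals, vecs = np.linalg.eigh(0.5 * (Cg + Cg.T))
    Cpos = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    M = np.linalg.solve(B.T @ B, B.T)
    out = M @ Cpos @ M.T
    return 0.5 * (out + out.T)


def pair_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Within-subject pair layout ``(j, j), (j, j+1), ..., (j, m)`` for ``j = 1..m``.

    Returns 0-based index arrays ``(j1, j2)`` of length ``m (m + 1) / 2``.
    """
    j1 = np.concatenate([np.full(m - j, j, dtype=int) for j in range(m)])
    j2 = np.concatenate([np.arange(j, m, dtype=int) for j in range(m)])
    return j1, j2


def subject_design(times: np.ndarray, basis: BSplineBasis, G: np.ndarray | None = None):
    """Design block ``X_i = [B_i G_c, delta_i]`` for one subject.

    Rows enumerate the pairs from :func:`pair_indices`; for coefficients
    ``alpha = (vech Theta, sigma2)`` the product ``X_i alpha`` equals
    ``H(t_{j1}, t_{j2}) + delta sigma2`` row-wise.

    Returns ``(X_i, delta_i, (j1, j2))``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("subject with no observations")
    if G is None:
        G = duplication_matrix(basis.n_basis)
    m = times.size
    B = eval_basis(basis, times)  # (m, c)
    j1, j2 = pair_indices(m)
    c = basis.n_basis
    # row for pair (j1, j2) is kron(b(t_{j2}), b(t_{j1})): index col*c + row
    rows = (B[j2][:, :, None] * B[j1][:, None, :]).reshape(len(j1), c * c)
    delta = (j1 == j2).astype(float)
    X = np.column_stack([rows @ G, delta])
    return X, delta, (j1, j2)
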