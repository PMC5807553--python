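"""Shared smoother factorization for penalized least squares.

For a penalized normal-equation matrix ``X'WX + lam * Q`` the factorization
``A' (X'WX) A = I`` and ``A' Q A = diag(s)`` gives

    (X'WX + lam Q)^{-1} = A [I + lam diag(s)]^{-1} A'

for every ``lam >= 0``; both ``A`` and ``s`` are free of ``lam``, so a whole
smoothing-parameter profile costs a single factorization.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import cholesky, eigh, solve_triangular

logger = logging.getLogger(__name__)

__all__ = ["smoother_decomposition", "default_lambda_grid"]


def smoother_decomposition(XtWX: np.ndarray, Q: np.ndarray, ridge: float = 1e-10):
    """Simultaneous diagonalization of a PD Gram matrix and a PSD penalty.

    Returns ``(A, s)`` with ``A' XtWX A = I`` and ``A' Q A = diag(s)``,
    ``s >= 0``.  A ridge of ``ridge * tr(XtWX)/K`` is added before the
    Cholesky factorization; rank deficiency beyond that raises.
    """
    K = XtWX.shape[0]
    shift = ridge * np.trace(XtWX) / K
    try:
        L = cholesky(XtWX + shift * np.eye(K), lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X'WX is rank deficient beyond the ridge tolerance; "
            "reduce the number of basis functions"
        ) from exc
    # L^{-1} Q L^{-T}, then an ordinary symmetric eigendecomposition
    Y = solve_triangular(L, Q, lower=True)
    Z = solve_triangular(L, Y.T, lower=True).T
    s, U = eigh(0.5 * (Z + Z.T))
    if np.min(s) < -1e-8 * max(1.0, np.max(np.abs(s))):
        logger.warning("penalty eigenvalues dip below zero: min %.3g", np.min(s))
    s = np.clip(s, 0.0, None)
    A = solve_triangular(L, U, lower=True, trans="T")
    return A, s


def default_lambda_grid(XtWX: np.ndarray, Q: np.ndarray, n: int = 100,
                        span: tuple[float, float] = (1e-8, 1e8)) -> np.ndarray:
    """Log-spaced smoothing-parameter grid scaled by ``tr(X'WX)/tr(Q)``."""
    ref = np.trace(XtWX) / max(np.trace(Q), np.finfo(float).tiny)
    return ref * np.logspace(np.log10(span[0]), np.log10(span[1]), n)
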