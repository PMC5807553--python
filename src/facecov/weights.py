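"""Gaussian covariance of the raw-covariance vector and stabilized weights.

Under the Gaussian model the residual products have, by Isserlis' theorem,

    cov(C_{i j1 j2}, C_{i j3 j4}) = R(j1,j3) R(j2,j4) + R(j1,j4) R(j2,j3),

with ``R(a, b) = C(t_a, t_b) + delta_ab sigma2``.  The second-stage weight for
subject ``i`` is the inverse of a diagonal-blended version of this matrix,
``W_i = [(1 - beta) cov + beta diag(cov)]^{-1}``, which is well conditioned
even when the plug-in covariance is nearly singular.  ``beta = 0.05`` by
default.
"""

from __future__ import annotations

import logging

import numpy as np

from .basis import pair_indices

__all__ = ["auxiliary_covariance", "build_weight", "subject_weights"]

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.05


def auxiliary_covariance(cov, sigma2: float, times: np.ndarray) -> np.ndarray:
    """Covariance matrix of one subject's raw-covariance vector.

    ``cov`` is a callable ``cov(s, t)`` accepting broadcastable arrays;
    ``times`` are the subject's observation times; the pair ordering matches
    :func:`facecov.basis.pair_indices`.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    times = np.asarray(times, dtype=float)
    m = times.size
    R = np.asarray(cov(times[:, None], times[None, :]), dtype=float)
    R = 0.5 * (R + R.T) + sigma2 * np.eye(m)
    j1, j2 = pair_indices(m)
    out = (
        R[np.ix_(j1, j1)] * R[np.ix_(j2, j2)]
        + R[np.ix_(j1, j2)] * R[np.ix_(j2, j1)]
    )
    return 0.5 * (out + out.T)


def build_weight(cov_Ci: np.ndarray, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Blend towards the diagonal and invert: ``W_i = [(1-b) V + b diag V]^{-1}``."""
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    d = np.diag(cov_Ci)
    if np.any(d <= 0):
        raise np.linalg.LinAlgError(
            "non-positive diagonal in the plug-in covariance of raw covariances"
        )
    V = (1.0 - beta) * cov_Ci + beta * np.diag(d)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        # plug-in indefiniteness: jitter the diagonal and retry
        jitter = 1e-8 * float(np.mean(d))
        logger.warning("blended weight matrix not PD; adding jitter %.3g", jitter)
        L = np.linalg.cholesky(V + jitter * np.eye(V.shape[0]))
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv


def subject_weights(cov, sigma2: float, times_list, beta: float = DEFAULT_BETA):
    """Per-subject weight blocks from a plug-in covariance function and noise."""
    return [build_weight(auxiliary_covariance(cov, sigma2, t), beta) for t in times_list]
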