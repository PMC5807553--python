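"""fPCA of the smoothed covariance and best-prediction of subject curves.

Eigenpairs of the covariance integral operator are approximated by the
Nyström method: evaluate ``C`` on a grid of ``g`` midpoints, eigendecompose
the kernel matrix scaled by the quadrature weight ``1/g`` and rescale
eigenvectors by ``sqrt(g)`` so they are orthonormal in L2[0, 1].

Subject curves ``X_i = f + u_i`` are predicted by the Gaussian conditional
expectation given the subject's sparse noisy observations,

    xhat_i = (H^n Theta H^o') V_i^{-1} (y_i - f_i^o) + f_i^n,
    V_i    = H^o Theta H^o' + sigma2 I,

with the conditional covariance giving pointwise bands.  Because the
penalized ``Theta`` need not be positive semidefinite, prediction uses a PSD
surrogate obtained by trimming negative eigenvalues of the covariance on a
grid and projecting back onto the tensor-spline coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .basis import eval_basis, psd_trim_theta
from .estimator import FacesSmoother

logger = logging.getLogger(__name__)

__all__ = [
    "EigenSystem",
    "CurvePrediction",
    "eigendecompose_on_grid",
    "psd_theta",
    "predict_curve",
    "pointwise_band",
]


@dataclass(frozen=True)
class EigenSystem:
    """Grid eigenpairs of a covariance operator.

    ``functions[:, l]`` is the ``l``-th eigenfunction on ``grid``, orthonormal
    under the quadrature inner product ``(1/g) sum``; eigenvalues are
    descending with negatives trimmed to zero.
    """

    grid: np.ndarray
    values: np.ndarray
    functions: np.ndarray  # (g, n_kept)
    weight: float

    def ise(self, other_fn, index: int) -> float:
        """Sign-invariant integrated squared error against a true eigenfunction."""
        from .simulation import eigenfunction_ise

        psi = np.asarray(other_fn(self.grid), dtype=float)
        return eigenfunction_ise(psi, self.functions[:, index], self.weight)


def _as_cov_callable(C):
    if isinstance(C, FacesSmoother):
        return lambda s, t: C.covariance(s, t)
    return C


def eigendecompose_on_grid(C, grid_size: int = 100) -> EigenSystem:
    """Nyström eigendecomposition of a covariance (fitted smoother or callable)."""
    g = grid_size
    grid = (np.arange(g) + 0.5) / g
    if isinstance(C, FacesSmoother):
        M = C.covariance(grid)
    else:
        M = np.asarray(C(grid[:, None], grid[None, :]), dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("covariance evaluations are not finite")
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T) / g)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order] * np.sqrt(g)  # L2-orthonormal on [0, 1]
    return EigenSystem(grid=grid, values=vals, functions=vecs, weight=1.0 / g)


def psd_theta(fit: FacesSmoother, grid_size: int = 100) -> np.ndarray:
    """PSD surrogate of ``theta_``: trim negative grid eigenvalues, project back.

    The trimmed grid covariance is mapped to coefficients by the least-squares
    projection ``Theta+ = M C+ M'`` with ``M = (B'B)^{-1} B'``, which preserves
    positive semidefiniteness.
    """
    return psd_trim_theta(fit.basis_, fit.theta_, grid_size)


@dataclass(frozen=True)
class CurvePrediction:
    """Predicted subject curve with pointwise uncertainty."""

    s: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def predict_curve(fit: FacesSmoother, times, y, s_new, level: float = 0.95,
                  theta: np.ndarray | None = None) -> CurvePrediction:
    """Conditional-expectation prediction of one subject's curve at ``s_new``.

    ``theta`` overrides the coefficient matrix (e.g. to plug in the truth);
    by default the PSD-trimmed surrogate of the fitted ``theta_`` is used.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    s_new = np.atleast_1d(np.asarray(s_new, dtype=float))
    if theta is None:
        cache = getattr(fit, "_theta_psd", None)
        if cache is None:
            cache = psd_theta(fit)
            fit._theta_psd = cache
        theta = cache
    sigma2 = float(fit.sigma2_)
    Ho = eval_basis(fit.basis_, times)
    Hn = eval_basis(fit.basis_, s_new)
    V = Ho @ theta @ Ho.T + sigma2 * np.eye(len(times))
    cross = Hn @ theta @ Ho.T
    try:
        gain = np.linalg.solve(V, cross.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "observation covariance is singular; consider a positive noise floor"
        ) from exc
    if fit.mean_ is None:
        fo = np.zeros(len(times))
        fn = np.zeros(len(s_new))
    else:
        fo = fit.mean_.predict(times)
        fn = fit.mean_.predict(s_new)
    mean = gain @ (y - fo) + fn
    Vn = Hn @ theta @ Hn.T + sigma2 * np.eye(len(s_new))
    cov = Vn - gain @ cross.T
    cov = 0.5 * (cov + cov.T)
    lower, upper = _band(mean, cov, level)
    return CurvePrediction(s=s_new, mean=mean, cov=cov, lower=lower, upper=upper)


def _band(mean, cov, level):
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return mean - half, mean + half


def pointwise_band(prediction: CurvePrediction, level: float = 0.95):
    """Symmetric Gaussian pointwise band around the predicted mean."""
    return _band(prediction.mean, prediction.cov, level)
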