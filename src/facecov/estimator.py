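"""FACEs: fast covariance estimation for sparse functional data.

The covariance surface ``C(s, t)`` and the error variance ``sigma2_eps`` are
estimated jointly by penalized (weighted) least squares on the raw residual
products,

    min_{Theta = Theta', sigma2}  (Chat - X alpha)' W (Chat - X alpha)
                                  + lam * ||Theta D||_F^2,

with ``alpha = (vech Theta, sigma2)``.  The smoothing parameter is chosen by a
fast approximation to leave-one-subject-out cross-validation (iGCV): after one
smoother factorization, every candidate ``lam`` is scored in O(n K^2) from
lam-free precomputed quantities.  A two-stage procedure first fits with
identity weights, then rebuilds the weights from the Gaussian covariance of
the residual products (Isserlis plug-in) and refits.

``FacesSmoother`` is the scikit-learn-style front end; the module-level
functions (``igcv``, ``solve_alpha``, ``select_lambda`` and the brute-force
oracles) expose the individual steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .basis import (
    BSplineBasis,
    eval_basis,
    make_basis,
    penalty_matrices,
    psd_trim_theta,
    subject_design,
    unvech,
)
from .io import FunctionalDataset, TimeTransform, as_dataset
from .linalg import default_lambda_grid, smoother_decomposition
from .mean import MeanPSpline
from .raw import RawCovariances, build_raw_covariances, compute_residuals
from .weights import DEFAULT_BETA, subject_weights

logger = logging.getLogger(__name__)

__all__ = [
    "PrecomputedGCV",
    "FacesSmoother",
    "build_precomputed",
    "igcv",
    "solve_alpha",
    "select_lambda",
    "effective_df",
    "igcv_direct_oracle",
    "icv_oracle",
    "fit_faces",
    "evaluate_covariance",
]


@dataclass
class PrecomputedGCV:
    """Smoothing-parameter-free quantities for the fast iGCV score.

    With ``F = X A`` and ``d = diag([I + lam diag(s)]^{-1})`` the fitted
    coefficients are ``alpha = A (d * ftil)`` and the iGCV score is a fixed
    quadratic/Hadamard expression in ``d`` built from the fields below; each
    evaluation costs O(n K^2).
    """

    A: np.ndarray
    s: np.ndarray
    ftil: np.ndarray  # F' W Chat
    f: np.ndarray  # F' Chat
    FtF: np.ndarray
    g: np.ndarray  # sum_i f_i * J_i
    G1: np.ndarray  # sum_i (J_i ftil') ⊙ L_i
    G2: np.ndarray  # sum_i (f_i ftil') ⊙ Ltil_i
    Lstack: np.ndarray  # (n, K, K): L_i = F_i' F_i
    Ltstack: np.ndarray  # (n, K, K): Ltil_i = F_i' W_i F_i
    C_sq: float  # ||Chat||^2
    n_obs: int
    XtWX: np.ndarray = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return len(self.s)


def build_precomputed(X_blocks, C_blocks, Q, W_blocks=None) -> PrecomputedGCV:
    """Assemble the lam-free iGCV quantities from per-subject design blocks."""
    K = X_blocks[0].shape[1]
    XtWX = np.zeros((K, K))
    XtWC = np.zeros(K)
    WC_blocks = []
    for i, (Xi, Ci) in enumerate(zip(X_blocks, C_blocks)):
        WCi = Ci if W_blocks is None else W_blocks[i] @ Ci
        WC_blocks.append(WCi)
        XtWX += Xi.T @ (Xi if W_blocks is None else W_blocks[i] @ Xi)
    XtWX = 0.5 * (XtWX + XtWX.T)
    A, s = smoother_decomposition(XtWX, Q)
    n = len(X_blocks)
    Lstack = np.empty((n, K, K))
    Ltstack = np.empty((n, K, K))
    f = np.zeros(K)
    ftil = np.zeros(K)
    g = np.zeros(K)
    f_list, J_list = [], []
    C_sq = 0.0
    n_obs = 0
    for i, (Xi, Ci, WCi) in enumerate(zip(X_blocks, C_blocks, WC_blocks)):
        Fi = Xi @ A
        WFi = Fi if W_blocks is None else W_blocks[i] @ Fi
        fi = Fi.T @ Ci
        Ji = Fi.T @ WCi
        Lstack[i] = Fi.T @ Fi
        Ltstack[i] = Fi.T @ WFi
        f += fi
        ftil += Ji
        g += fi * Ji
        f_list.append(fi)
        J_list.append(Ji)
        C_sq += float(Ci @ Ci)
        n_obs += len(Ci)
    FtF = Lstack.sum(axis=0)
    G1 = np.einsum("ik,l,ikl->kl", np.array(J_list), ftil, Lstack)
    G2 = np.einsum("ik,l,ikl->kl", np.array(f_list), ftil, Ltstack)
    return PrecomputedGCV(
        A=A, s=s, ftil=ftil, f=f, FtF=FtF, g=g, G1=G1, G2=G2,
        Lstack=Lstack, Ltstack=Ltstack, C_sq=C_sq, n_obs=n_obs, XtWX=XtWX,
    )


def igcv(precomp: PrecomputedGCV, lam: float) -> float:
    """Fast leave-one-subject-out GCV score at one smoothing parameter.

    Exactly equals the direct smoother-matrix form (:func:`igcv_direct_oracle`)
    but costs O(n K^2) given the precomputation.
    """
    d = 1.0 / (1.0 + lam * precomp.s)
    v = precomp.ftil * d
    Lv = precomp.Lstack @ v
    Ltv = precomp.Ltstack @ v
    return float(
        precomp.C_sq
        - 2.0 * d @ (precomp.ftil * precomp.f)
        + v @ precomp.FtF @ v
        + 2.0 * d @ precomp.g
        - 2.0 * d @ ((precomp.G1 + precomp.G2) @ d)
        + 2.0 * d @ ((Lv * Ltv).sum(axis=0))
    )


def solve_alpha(precomp: PrecomputedGCV, lam: float) -> np.ndarray:
    """Penalized (weighted) least-squares coefficients ``alpha = (theta, sigma2)``."""
    d = 1.0 / (1.0 + lam * precomp.s)
    return precomp.A @ (d * precomp.ftil)


def effective_df(precomp: PrecomputedGCV, lam: float) -> float:
    """Trace of the smoother, ``sum_k 1 / (1 + lam s_k)``; decreasing in lam."""
    return float(np.sum(1.0 / (1.0 + lam * precomp.s)))


def select_lambda(precomp: PrecomputedGCV, grid) -> tuple[float, np.ndarray]:
    """Grid argmin of iGCV; ties break towards the larger (smoother) lam."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty smoothing-parameter grid")
    scores = np.array([igcv(precomp, lam) for lam in grid])
    smin = float(np.min(scores))
    # near-ties (numerical noise on a flat profile, relative to the score's
    # leading term ||Chat||^2) resolve to the smoother fit
    thresh = smin + 1e-12 * max(precomp.C_sq, np.finfo(float).tiny)
    best = int(np.max(np.flatnonzero(scores <= thresh)))
    return float(grid[best]), scores


# ---------------------------------------------------------------------------
# Brute-force oracles (small instances; used for validation)

_ORACLE_CAP = 4000


def _smoother_pieces(X, W, Q, lam, offsets):
    N = X.shape[0]
    if N > _ORACLE_CAP:
        raise ValueError(f"oracle refuses N={N} > {_ORACLE_CAP}")
    H = np.linalg.solve(X.T @ W @ X + lam * Q, X.T @ W)
    S = X @ H
    blocks = [slice(offsets[i], offsets[i + 1]) for i in range(len(offsets) - 1)]
    return S, blocks


def igcv_direct_oracle(X, W, Q, C, lam, offsets) -> float:
    """Literal smoother-matrix evaluation of the iGCV criterion."""
    S, blocks = _smoother_pieces(X, W, Q, lam, offsets)
    resid = S @ C - C
    total = float(resid @ resid)
    for b in blocks:
        Sii = S[b, b]
        r = resid[b]
        total += 2.0 * float(r @ Sii @ r)
    return total


def icv_oracle(X, W, Q, C, lam, offsets) -> float:
    """Exact leave-one-subject-out CV via the block hat-matrix identity."""
    S, blocks = _smoother_pieces(X, W, Q, lam, offsets)
    resid = S @ C - C
    total = 0.0
    for b in blocks:
        Sii = S[b, b]
        r = np.linalg.solve(np.eye(Sii.shape[0]) - Sii, resid[b])
        total += float(r @ r)
    return total


# ---------------------------------------------------------------------------


class _KnownMean:
    """Adapter giving a plain callable the ``predict`` surface."""

    def __init__(self, fn):
        self._fn = fn

    def predict(self, t):
        return np.asarray(self._fn(np.asarray(t, dtype=float)), dtype=float)


class FacesSmoother(BaseEstimator):
    """Symmetric tensor-product P-spline covariance smoother (FACEs).

    Parameters
    ----------
    n_basis : int, default 10
        Marginal B-spline basis size ``c`` (interior knots + order).
    degree : int, default 3
        Marginal spline degree.
    beta : float, default 0.05
        Diagonal blend of the second-stage weight matrices.
    n_lambda : int, default 100
        Size of the log-spaced smoothing-parameter grid (1e-8..1e8 times a
        data-scaled reference).
    mean : {"pspline", "zero", "known"}, default "pspline"
        Mean handling; ``known`` uses ``mean_model`` (a callable ``f(t)``).
    two_stage : bool, default True
        Re-weight by the plug-in Gaussian covariance of the residual products
        and refit; ``False`` stops after the unweighted stage.

    Attributes
    ----------
    theta_ : ndarray of shape (c, c)
        Symmetric spline coefficient matrix of the covariance surface.
    sigma2_ : float
        Estimated measurement-error variance (clamped at 0).
    lambda_ : tuple of float
        Selected smoothing parameter per stage.
    mean_ : MeanPSpline or None
        The fitted (or supplied) mean model; None encodes a zero mean.
    igcv_profiles_ : list of (grid, scores)
        iGCV profiles per stage, for diagnostics.
    edf_ : float
        Effective degrees of freedom of the final smoother.
    """

    def __init__(self, n_basis: int = 10, degree: int = 3, beta: float = DEFAULT_BETA,
                 n_lambda: int = 100, mean: str = "pspline", two_stage: bool = True,
                 mean_model=None):
        self.n_basis = n_basis
        self.degree = degree
        self.beta = beta
        self.n_lambda = n_lambda
        self.mean = mean
        self.two_stage = two_stage
        self.mean_model = mean_model

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        ds: FunctionalDataset = as_dataset(X)
        if np.any(ds.t < 0) or np.any(ds.t > 1):
            raise ValueError("times must be rescaled to [0, 1] before fitting")
        if int(np.sum(ds.counts >= 2)) < 2:
            raise ValueError(
                "need at least two subjects with two or more observations "
                "(no off-diagonal information)"
            )
        if self.mean == "pspline":
            mean = MeanPSpline(n_basis=self.n_basis, degree=self.degree).fit(ds)
        elif self.mean == "zero":
            mean = None
        elif self.mean == "known":
            if self.mean_model is None:
                raise ValueError("mean='known' requires mean_model")
            mean = (
                self.mean_model
                if hasattr(self.mean_model, "predict")
                else _KnownMean(self.mean_model)
            )
        else:
            raise ValueError(f"unknown mean option {self.mean!r}")

        basis = make_basis(self.n_basis, self.degree)
        pen = penalty_matrices(basis)
        residuals = compute_residuals(ds, mean)
        raw = build_raw_covariances(ds, residuals)
        X_blocks = [
            subject_design(t_i, basis, pen.G)[0] for t_i in raw.times
        ]
        C_blocks = [raw.values[raw.subject_slice(i)] for i in range(len(raw.times))]

        lambdas, profiles = [], []

        # stage 1: identity weights
        pre1 = build_precomputed(X_blocks, C_blocks, pen.Q)
        grid1 = default_lambda_grid(pre1.XtWX, pen.Q, self.n_lambda)
        lam1, sc1 = select_lambda(pre1, grid1)
        alpha1 = solve_alpha(pre1, lam1)
        lambdas.append(lam1)
        profiles.append((grid1, sc1))
        theta1 = unvech(alpha1[:-1], self.n_basis)
        sigma2_1 = float(alpha1[-1])
        pre, alpha = pre1, alpha1

        if self.two_stage:
            # plug-in covariance scale for the noise floor
            probe = np.linspace(0.0, 1.0, 51)
            Bp = eval_basis(basis, probe)
            diag1 = np.einsum("ij,jk,ik->i", Bp, theta1, Bp)
            scale = max(float(np.mean(np.abs(diag1))), 1e-12)
            sigma2_plug = max(sigma2_1, 1e-6 * scale)
            # PSD-trimmed plug-in keeps the Isserlis matrices true covariances
            cov1 = _theta_cov(basis, psd_trim_theta(basis, theta1))
            W_blocks = subject_weights(cov1, sigma2_plug, raw.times, self.beta)
            pre = build_precomputed(X_blocks, C_blocks, pen.Q, W_blocks)
            grid2 = default_lambda_grid(pre.XtWX, pen.Q, self.n_lambda)
            lam2, sc2 = select_lambda(pre, grid2)
            alpha = solve_alpha(pre, lam2)
            lambdas.append(lam2)
            profiles.append((grid2, sc2))

        self.basis_: BSplineBasis = basis
        self.mean_ = mean
        self.raw_: RawCovariances = raw
        self.theta_ = unvech(alpha[:-1], self.n_basis)
        self.sigma2_ = max(float(alpha[-1]), 0.0)
        self.theta_stage1_ = theta1
        self.sigma2_stage1_ = max(sigma2_1, 0.0)
        self.lambda_ = tuple(lambdas)
        self.igcv_profiles_ = profiles
        self.edf_ = effective_df(pre, lambdas[-1])
        self.time_transform_ = ds.time_transform
        return self

    # -- evaluation ---------------------------------------------------------

    def covariance(self, s, t=None) -> np.ndarray:
        """Smoothed covariance ``C(s, t) = b(s)' Theta b(t)``.

        With ``t=None`` returns the full grid ``C[i, j] = C(s_i, s_j)``;
        otherwise ``s`` and ``t`` pair up elementwise.
        """
        Bs = eval_basis(self.basis_, np.atleast_1d(np.asarray(s, dtype=float)))
        if t is None:
            M = Bs @ self.theta_ @ Bs.T
            return 0.5 * (M + M.T)
        Bt = eval_basis(self.basis_, np.atleast_1d(np.asarray(t, dtype=float)))
        # evaluate both orientations and average: symmetry exact in floats
        fwd = np.einsum("ij,jk,ik->i", Bs, self.theta_, Bt)
        rev = np.einsum("ij,jk,ik->i", Bt, self.theta_, Bs)
        return 0.5 * (fwd + rev)

    def predict(self, times, y, s_new):
        """Best prediction of one subject's curve; see :func:`facecov.fpca.predict_curve`."""
        from .fpca import predict_curve

        return predict_curve(self, times, y, s_new)


def _theta_cov(basis: BSplineBasis, theta: np.ndarray):
    def cov(s, t):
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        s_b, t_b = np.broadcast_arrays(s, t)
        Bs = eval_basis(basis, s_b.ravel())
        Bt = eval_basis(basis, t_b.ravel())
        return np.einsum("ij,jk,ik->i", Bs, theta, Bt).reshape(s_b.shape)

    return cov


def fit_faces(data, **params) -> FacesSmoother:
    """Functional wrapper: fit a :class:`FacesSmoother` on long-format data."""
    return FacesSmoother(**params).fit(data)


def evaluate_covariance(fit: FacesSmoother, s, t=None) -> np.ndarray:
    """Evaluate a fitted smoother's covariance surface."""
    return fit.covariance(s, t)
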