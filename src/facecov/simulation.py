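"""Simulation harness: sparse Gaussian functional data and evaluation criteria.

Data follow ``y_ij = f(t_ij) + u_i(t_ij) + eps_ij`` with ``f(t) = 5 sin(2 pi t)``,
``u_i`` a zero-mean Gaussian process and white noise ``eps``.  Two covariance
cases are available:

* case 1 — a rank-3 Karhunen–Loeve construction with eigenvalues
  ``0.5^(l-1)`` and trigonometric eigenfunctions ``sqrt(2) sin(2 pi t)``,
  ``sqrt(2) cos(4 pi t)``, ``sqrt(2) sin(4 pi t)``;
* case 2 — a Matérn covariance with range 0.07 and order 1 (classical
  Handcock–Stein parameterization), sampled by Cholesky factorization at the
  drawn time points.

The noise level is fixed by a signal-to-noise rule on the trace,
``sigma2_eps = (1/SNR) * int C(t, t) dt`` (1.75/SNR in case 1, 1/SNR in
case 2).  Per-subject counts are uniform on {3..7} (mean 5) or {5..15}
(mean 10), and times are i.i.d. uniform on [0, 1].

Fits are scored by four criteria: integrated squared error (ISE) of the
covariance surface, sign-invariant ISEs of the top-3 eigenfunctions, squared
errors of the top-3 eigenvalues, and the curve-prediction ISE on held-out
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv

from .estimator import FacesSmoother
from .fpca import eigendecompose_on_grid, predict_curve
from .io import FunctionalDataset

__all__ = [
    "SimulationConfig",
    "TruthModel",
    "CriterionReport",
    "mean_function",
    "case1_eigenfunctions",
    "CASE1_EIGENVALUES",
    "true_cov_case1",
    "matern_cov",
    "sigma2_from_snr",
    "make_truth",
    "generate_dataset",
    "cov_ise",
    "eigenfunction_ise",
    "eigenvalue_se",
    "curve_prediction_ise",
    "run_replications",
]


def mean_function(t):
    """Population mean ``f(t) = 5 sin(2 pi t)``."""
    return 5.0 * np.sin(2.0 * np.pi * np.asarray(t, dtype=float))


CASE1_EIGENVALUES = np.array([1.0, 0.5, 0.25])


def case1_eigenfunctions():
    """The three orthonormal trigonometric eigenfunctions of case 1."""
    return [
        lambda t: np.sqrt(2.0) * np.sin(2.0 * np.pi * np.asarray(t, dtype=float)),
        lambda t: np.sqrt(2.0) * np.cos(4.0 * np.pi * np.asarray(t, dtype=float)),
        lambda t: np.sqrt(2.0) * np.sin(4.0 * np.pi * np.asarray(t, dtype=float)),
    ]


def true_cov_case1(s, t):
    """Rank-3 covariance ``sum_l 0.5^(l-1) psi_l(s) psi_l(t)``."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(s.shape, t.shape))
    for lam, psi in zip(CASE1_EIGENVALUES, case1_eigenfunctions()):
        out = out + lam * psi(s) * psi(t)
    return out


def matern_cov(d, phi: float = 0.07, nu: float = 1.0):
    """Matérn correlation ``(d/phi)^nu K_nu(d/phi) / (2^(nu-1) Gamma(nu))``.

    Classical (Handcock–Stein) parameterization with range ``phi`` and order
    ``nu``; equals 1 at ``d = 0`` by continuity.
    """
    if phi <= 0 or nu <= 0:
        raise ValueError("phi and nu must be positive")
    d = np.asarray(d, dtype=float)
    z = d / phi
    with np.errstate(invalid="ignore"):
        val = z**nu * kv(nu, z) / (2.0 ** (nu - 1.0) * gamma_fn(nu))
    return np.where(z < 1e-12, 1.0, val)


def sigma2_from_snr(cov, snr: float, n_quad: int = 2000) -> float:
    """Noise variance from the trace rule ``sigma2 = (1/snr) int C(t,t) dt``."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    t = (np.arange(n_quad) + 0.5) / n_quad
    trace = float(np.mean(cov(t, t)))
    return trace / snr


@dataclass(frozen=True)
class TruthModel:
    """The generating model: mean, covariance, noise and (if analytic) eigenpairs."""

    mean: callable
    cov: callable
    sigma2: float
    eigenvalues: np.ndarray | None = None
    eigenfunctions: list | None = None

    def eigen_on_grid(self, grid: np.ndarray):
        """True top eigenpairs evaluated on ``grid`` (analytic or Nyström)."""
        if self.eigenfunctions is not None:
            vals = np.asarray(self.eigenvalues, dtype=float)
            funs = np.column_stack([psi(grid) for psi in self.eigenfunctions])
            return vals, funs
        g = len(grid)
        M = self.cov(grid[:, None], grid[None, :])
        vals, vecs = np.linalg.eigh(M / g)
        order = np.argsort(vals)[::-1]
        return np.clip(vals[order], 0.0, None), vecs[:, order] * np.sqrt(g)


def make_truth(case: int, snr: float) -> TruthModel:
    if case == 1:
        cov = true_cov_case1
        return TruthModel(
            mean=mean_function,
            cov=cov,
            sigma2=sigma2_from_snr(lambda s, t: cov(s, t), snr),
            eigenvalues=CASE1_EIGENVALUES,
            eigenfunctions=case1_eigenfunctions(),
        )
    if case == 2:
        cov = lambda s, t: matern_cov(np.abs(np.asarray(s, float) - np.asarray(t, float)))
        return TruthModel(mean=mean_function, cov=cov, sigma2=sigma2_from_snr(cov, snr))
    raise ValueError(f"unknown simulation case {case!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation setting."""

    case: int = 1
    n: int = 100
    m_set: tuple = (3, 4, 5, 6, 7)
    snr: float = 2.0
    n_test: int = 200

    def __post_init__(self):
        if len(self.m_set) == 0 or min(self.m_set) < 1:
            raise ValueError("m_set must be non-empty integers >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def generate_dataset(config: SimulationConfig, rng, n_subjects: int | None = None,
                     curve_grid: np.ndarray | None = None):
    """Draw one dataset; optionally retain true curves on ``curve_grid``.

    Returns ``(dataset, truth, curves)`` where ``curves`` is an
    ``(n, len(curve_grid))`` array of true subject curves ``X_i = f + u_i``
    (or None).  Case 1 samples Karhunen–Loeve scores, so curves are exact
    anywhere; case 2 samples ``u_i`` jointly at the observation times and the
    requested grid by Cholesky factorization (1e-10 jitter).
    """
    truth = make_truth(config.case, config.snr)
    n = config.n if n_subjects is None else n_subjects
    m = rng.choice(np.asarray(config.m_set), size=n)
    subjects, times, values = [], [], []
    curves = None if curve_grid is None else np.empty((n, len(curve_grid)))
    for i in range(n):
        t_i = np.sort(rng.uniform(0.0, 1.0, size=m[i]))
        if config.case == 1:
            z = rng.standard_normal(3) * np.sqrt(CASE1_EIGENVALUES)
            u_i = sum(
                z[l] * psi(t_i) for l, psi in enumerate(case1_eigenfunctions())
            )
            if curves is not None:
                curves[i] = truth.mean(curve_grid) + sum(
                    z[l] * psi(curve_grid)
                    for l, psi in enumerate(case1_eigenfunctions())
                )
        else:
            pts = t_i if curves is None else np.concatenate([t_i, curve_grid])
            K = truth.cov(pts[:, None], pts[None, :]) + 1e-10 * np.eye(len(pts))
            u = np.linalg.cholesky(K) @ rng.standard_normal(len(pts))
            u_i = u[: len(t_i)]
            if curves is not None:
                curves[i] = truth.mean(curve_grid) + u[len(t_i):]
        y_i = truth.mean(t_i) + u_i + rng.normal(0.0, np.sqrt(truth.sigma2), size=m[i])
        subjects.append(np.full(m[i], i))
        times.append(t_i)
        values.append(y_i)
    ds = FunctionalDataset(
        subjects=np.concatenate(subjects),
        t=np.concatenate(times),
        y=np.concatenate(values),
    )
    return ds, truth, curves


# ---------------------------------------------------------------------------
# Criteria


def cov_ise(C_hat: np.ndarray, C_true: np.ndarray, weight: float) -> float:
    """Quadrature ISE of a covariance surface over the unit square."""
    C_hat = np.asarray(C_hat, dtype=float)
    C_true = np.asarray(C_true, dtype=float)
    if C_hat.shape != C_true.shape:
        raise ValueError("covariance grids have different shapes")
    return float(np.sum((C_hat - C_true) ** 2) * weight**2)


def eigenfunction_ise(psi: np.ndarray, psi_hat: np.ndarray, weight: float) -> float:
    """Sign-invariant ISE ``min(int (psi - psihat)^2, int (psi + psihat)^2)`` in [0, 2]."""
    psi = np.asarray(psi, dtype=float)
    psi_hat = np.asarray(psi_hat, dtype=float)
    for v in (psi, psi_hat):
        norm = np.sum(v**2) * weight
        if abs(norm - 1.0) > 1e-3:
            raise ValueError(f"eigenfunction not L2-normalized (norm^2 = {norm:.6f})")
    minus = np.sum((psi - psi_hat) ** 2) * weight
    plus = np.sum((psi + psi_hat) ** 2) * weight
    return float(min(minus, plus))


def eigenvalue_se(lam: float, lam_hat: float) -> float:
    """Squared error of one eigenvalue."""
    return float((lam - lam_hat) ** 2)


def curve_prediction_ise(fit: FacesSmoother, test_ds: FunctionalDataset,
                         true_curves: np.ndarray, grid: np.ndarray) -> float:
    """Mean over test subjects of ``int (Xhat_i - X_i)^2`` on the given grid."""
    scores = []
    for i, rows in enumerate(test_ds.groups):
        pred = predict_curve(fit, test_ds.t[rows], test_ds.y[rows], grid)
        scores.append(float(np.trapezoid((pred.mean - true_curves[i]) ** 2, grid)))
    return float(np.mean(scores))


PREDICTION_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class CriterionReport:
    """Per-replicate criteria and their median/IQR summaries."""

    cov_ise: np.ndarray
    eigenfunction_ise: np.ndarray  # (reps, 3)
    eigenvalue_se: np.ndarray  # (reps, 3)
    prediction_ise: np.ndarray | None
    sigma2: np.ndarray
    n_failed: int = 0
    summary: dict = field(default_factory=dict)

    def summarize(self):
        def med_iqr(x):
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            return {"median": float(med), "iqr": float(q3 - q1)}

        self.summary = {
            "cov_ise": med_iqr(self.cov_ise),
            "sigma2": med_iqr(self.sigma2),
            "eigenfunction_ise": [med_iqr(self.eigenfunction_ise[:, l]) for l in range(3)],
            "eigenvalue_se": [med_iqr(self.eigenvalue_se[:, l]) for l in range(3)],
        }
        if self.prediction_ise is not None:
            self.summary["prediction_ise"] = med_iqr(self.prediction_ise)
        return self.summary


def run_replications(config: SimulationConfig, n_replicates: int = 200, seed: int = 0,
                     two_stage: bool = True, mean: str = "pspline",
                     with_prediction: bool = True, grid_size: int = 100,
                     n_lambda: int = 100) -> CriterionReport:
    """Generate, fit and score ``n_replicates`` datasets under one setting."""
    eig_grid = (np.arange(grid_size) + 0.5) / grid_size
    covs, sig2s, ef_ises, ev_ses, pred_ises = [], [], [], [], []
    n_failed = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        ds, truth, _ = generate_dataset(config, rng)
        try:
            fit = FacesSmoother(
                two_stage=two_stage, mean=mean, mean_model=truth.mean,
                n_lambda=n_lambda,
            ).fit(ds)
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        C_hat = fit.covariance(eig_grid)
        C_true = truth.cov(eig_grid[:, None], eig_grid[None, :])
        covs.append(cov_ise(C_hat, C_true, 1.0 / grid_size))
        sig2s.append(fit.sigma2_)
        eig = eigendecompose_on_grid(fit, grid_size)
        tvals, tfuns = truth.eigen_on_grid(eig_grid)
        ef_ises.append(
            [
                eigenfunction_ise(tfuns[:, l], eig.functions[:, l], eig.weight)
                for l in range(3)
            ]
        )
        ev_ses.append([eigenvalue_se(tvals[l], eig.values[l]) for l in range(3)])
        if with_prediction and config.n_test > 0:
            test_ds, _, curves = generate_dataset(
                config, rng, n_subjects=config.n_test, curve_grid=PREDICTION_GRID
            )
            pred_ises.append(
                curve_prediction_ise(fit, test_ds, curves, PREDICTION_GRID)
            )
    report = CriterionReport(
        cov_ise=np.asarray(covs),
        eigenfunction_ise=np.asarray(ef_ises),
        eigenvalue_se=np.asarray(ev_ses),
        prediction_ise=np.asarray(pred_ises) if pred_ises else None,
        sigma2=np.asarray(sig2s),
        n_failed=n_failed,
    )
    report.summarize()
    return report
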