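import numpy as np
import pytest

from conftest import full_weight, random_instance
from facecov.basis import make_basis, vech
from facecov.estimator import (
    FacesSmoother,
    build_precomputed,
    effective_df,
    fit_faces,
    icv_oracle,
    igcv,
    igcv_direct_oracle,
    select_lambda,
    solve_alpha,
)
from facecov.io import FunctionalDataset
from facecov.linalg import default_lambda_grid, smoother_decomposition
from facecov.simulation import SimulationConfig, generate_dataset


class TestSmootherDecomposition:
    @pytest.mark.parametrize("lam", [0.0, 1.0, 10.0])
    def test_factorized_inverse_matches_direct(self, rng, lam):
        K = 8
        R = rng.normal(size=(K, K))
        XtWX = R @ R.T + np.eye(K)
        Rq = rng.normal(size=(K, K - 2))
        Q = Rq @ Rq.T
        A, s = smoother_decomposition(XtWX, Q, ridge=0.0)
        inv_fact = (A / (1.0 + lam * s)) @ A.T
        np.testing.assert_allclose(
            inv_fact, np.linalg.inv(XtWX + lam * Q), atol=1e-8
        )

    def test_zero_penalty_gives_zero_s(self, rng):
        R = rng.normal(size=(5, 5))
        A, s = smoother_decomposition(R @ R.T + np.eye(5), np.zeros((5, 5)))
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_projection_trace_at_lambda_zero(self, rng):
        inst = random_instance(rng, n_subjects=10, m=3, n_basis=4)
        pre = build_precomputed(inst["X_blocks"], inst["C_blocks"], inst["pen"].Q)
        assert effective_df(pre, 0.0) == pytest.approx(inst["pen"].Q.shape[0], rel=1e-6)


class TestSolveAlpha:
    def test_lambda_zero_is_ols(self, rng):
        inst = random_instance(rng, n_subjects=12, m=3, n_basis=4)
        pre = build_precomputed(inst["X_blocks"], inst["C_blocks"], inst["pen"].Q)
        X, C = inst["X"], inst["C"]
        ols = np.linalg.lstsq(X, C, rcond=None)[0]
        np.testing.assert_allclose(solve_alpha(pre, 0.0), ols, atol=1e-6)

    def test_matches_direct_penalized_solve(self, rng):
        inst = random_instance(rng, n_subjects=10, m=4, n_basis=5, weighted=True)
        pre = build_precomputed(
            inst["X_blocks"], inst["C_blocks"], inst["pen"].Q, inst["W_blocks"]
        )
        W = full_weight(inst)
        X, C, Q = inst["X"], inst["C"], inst["pen"].Q
        lam = 3.7
        direct = np.linalg.solve(X.T @ W @ X + lam * Q, X.T @ W @ C)
        np.testing.assert_allclose(solve_alpha(pre, lam), direct, atol=1e-7)

    def test_huge_lambda_gives_bilinear_theta(self, rng):
        inst = random_instance(rng, n_subjects=30, m=4, n_basis=6)
        pre = build_precomputed(inst["X_blocks"], inst["C_blocks"], inst["pen"].Q)
        alpha = solve_alpha(pre, 1e12)
        from facecov.basis import unvech

        theta = unvech(alpha[:-1], 6)
        scale = max(np.max(np.abs(theta)), 1e-12)
        assert np.max(np.abs(np.diff(theta, 2, axis=0))) < 1e-6 * scale
        assert np.max(np.abs(np.diff(theta, 2, axis=1))) < 1e-6 * scale


class TestIGCV:
    @pytest.mark.parametrize("weighted", [False, True])
    def test_fast_equals_direct_oracle(self, rng, weighted):
        inst = random_instance(rng, n_subjects=20, m=4, n_basis=5, weighted=weighted)
        pre = build_precomputed(
            inst["X_blocks"], inst["C_blocks"], inst["pen"].Q, inst["W_blocks"]
        )
        W = full_weight(inst)
        grid = default_lambda_grid(pre.XtWX, inst["pen"].Q, 7)
        for lam in np.concatenate([[0.0], grid]):
            direct = igcv_direct_oracle(
                inst["X"], W, inst["pen"].Q, inst["C"], lam, inst["offsets"]
            )
            assert igcv(pre, lam) == pytest.approx(direct, rel=1e-6)

    def test_quadratic_homogeneity_in_response(self, rng):
        inst = random_instance(rng, n_subjects=8, m=3, n_basis=4)
        pre1 = build_precomputed(inst["X_blocks"], inst["C_blocks"], inst["pen"].Q)
        pre2 = build_precomputed(
            inst["X_blocks"], [2 * c for c in inst["C_blocks"]], inst["pen"].Q
        )
        assert igcv(pre2, 1.3) == pytest.approx(4 * igcv(pre1, 1.3), rel=1e-10)

    def test_single_subject_formula_evaluates(self, rng):
        inst = random_instance(rng, n_subjects=1, m=4, n_basis=4)
        val = igcv_direct_oracle(
            inst["X"], np.eye(len(inst["C"])), inst["pen"].Q, inst["C"], 1.0,
            inst["offsets"],
        )
        assert np.isfinite(val)

    def test_igcv_first_order_approximates_icv(self, rng):
        """With many subjects the leverages are small and iGCV tracks iCV."""
        inst = random_instance(rng, n_subjects=40, m=3, n_basis=5)
        W = np.eye(len(inst["C"]))
        lam = default_lambda_grid(
            build_precomputed(inst["X_blocks"], inst["C_blocks"], inst["pen"].Q).XtWX,
            inst["pen"].Q, 3,
        )[1]
        icv = icv_oracle(inst["X"], W, inst["pen"].Q, inst["C"], lam, inst["offsets"])
        gcv = igcv_direct_oracle(inst["X"], W, inst["pen"].Q, inst["C"], lam, inst["offsets"])
        assert abs(gcv - icv) / icv < 0.15


class TestICVOracle:
    def test_lemma_identity_equals_literal_refit(self, rng):
        inst = random_instance(rng, n_subjects=5, m=2, n_basis=4)
        X, C, Q, offs = inst["X"], inst["C"], inst["pen"].Q, inst["offsets"]
        W = np.eye(len(C))
        for lam in [0.1, 0.7, 5.0]:
            lemma = icv_oracle(X, W, Q, C, lam, offs)
            literal = 0.0
            for i in range(5):
                keep = np.ones(len(C), bool)
                keep[offs[i]:offs[i + 1]] = False
                a = np.linalg.solve(
                    X[keep].T @ X[keep] + lam * Q, X[keep].T @ C[keep]
                )
                literal += float(np.sum((X[~keep] @ a - C[~keep]) ** 2))
            assert lemma == pytest.approx(literal, abs=1e-8 * max(1.0, literal))

    def test_classical_loo_identity(self, rng):
        """One observation per subject, orthonormal design: leverages are 1/n."""
        n = 16
        Xcol = np.ones((n, 1)) / np.sqrt(n)
        C = rng.normal(size=n)
        Q = np.zeros((1, 1))
        offs = list(range(n + 1))
        icv = icv_oracle(Xcol, np.eye(n), Q, C, 0.0, offs)
        resid = Xcol @ (Xcol.T @ C) - C
        classical = float(np.sum((resid / (1 - 1 / n)) ** 2))
        assert icv == pytest.approx(classical, rel=1e-10)


class TestSelectLambda:
    def test_single_value_grid(self, rng):
        inst = random_instance(rng, n_subjects=6, m=3, n_basis=4)
        pre = build_precomputed(inst["X_blocks"], inst["C_blocks"], inst["pen"].Q)
        lam, scores = select_lambda(pre, [2.5])
        assert lam == 2.5 and len(scores) == 1

    def test_argmin_matches_direct_oracle(self, rng):
        inst = random_instance(rng, n_subjects=10, m=3, n_basis=5, weighted=True)
        pre = build_precomputed(
            inst["X_blocks"], inst["C_blocks"], inst["pen"].Q, inst["W_blocks"]
        )
        W = full_weight(inst)
        grid = default_lambda_grid(pre.XtWX, inst["pen"].Q, 12)
        lam, _ = select_lambda(pre, grid)
        direct = [
            igcv_direct_oracle(inst["X"], W, inst["pen"].Q, inst["C"], l, inst["offsets"])
            for l in grid
        ]
        assert lam == grid[int(np.argmin(direct))]

    def test_linear_truth_selects_heavy_smoothing(self):
        """Noiseless covariance linear in s and t: the argmin sits at the top of the grid."""
        r = np.random.default_rng(1)
        basis = make_basis(6, 3)
        from facecov.basis import penalty_matrices, subject_design

        pen = penalty_matrices(basis)
        k = np.arange(6.0)
        theta_lin = 0.2 + 0.1 * (k[:, None] + k[None, :])
        alpha = np.concatenate([vech(theta_lin), [0.0]])
        Xb, Cb = [], []
        for _ in range(25):
            t = np.sort(r.uniform(0, 1, 3))
            X, _, _ = subject_design(t, basis, pen.G)
            Xb.append(X)
            Cb.append(X @ alpha)
        pre = build_precomputed(Xb, Cb, pen.Q)
        grid = default_lambda_grid(pre.XtWX, pen.Q, 30)
        lam, _ = select_lambda(pre, grid)
        assert lam >= grid[-3]

    def test_effective_df_decreasing_in_lambda(self, rng):
        inst = random_instance(rng, n_subjects=10, m=3, n_basis=5)
        pre = build_precomputed(inst["X_blocks"], inst["C_blocks"], inst["pen"].Q)
        grid = default_lambda_grid(pre.XtWX, inst["pen"].Q, 20)
        dfs = [effective_df(pre, lam) for lam in grid]
        assert np.all(np.diff(dfs) < 0)


@pytest.fixture(scope="module")
def fitted():
    ds, truth, _ = generate_dataset(
        SimulationConfig(case=1, n=200), np.random.default_rng(17)
    )
    return FacesSmoother(n_lambda=40).fit(ds), truth


class TestFitFaces:
    def test_theta_exactly_symmetric(self, fitted):
        fit, _ = fitted
        np.testing.assert_array_equal(fit.theta_, fit.theta_.T)

    def test_sigma2_nonnegative_and_plausible(self, fitted):
        fit, truth = fitted
        assert fit.sigma2_ >= 0
        assert abs(fit.sigma2_ - truth.sigma2) < 0.5

    def test_local_optimality_of_solution(self, fitted, rng):
        """The penalized objective cannot be improved by perturbing alpha."""
        ds, truth, _ = generate_dataset(
            SimulationConfig(case=1, n=20), np.random.default_rng(23)
        )
        fit = FacesSmoother(n_lambda=10, mean="zero").fit(ds)
        from facecov.basis import penalty_matrices, subject_design
        from facecov.raw import build_raw_covariances

        pen = penalty_matrices(fit.basis_)
        raw = build_raw_covariances(ds, ds.y)
        Xb = [subject_design(t, fit.basis_, pen.G)[0] for t in raw.times]
        X = np.vstack(Xb)
        lam = fit.lambda_[0]

        def objective(alpha):
            r = raw.values - X @ alpha
            return float(r @ r + lam * alpha @ pen.Q @ alpha)

        # stage-1 solution of the unweighted objective
        pre = build_precomputed(Xb, [raw.values[raw.subject_slice(i)] for i in range(len(Xb))], pen.Q)
        alpha_hat = solve_alpha(pre, lam)
        base = objective(alpha_hat)
        for _ in range(10):
            assert objective(alpha_hat + 1e-3 * rng.normal(size=len(alpha_hat))) >= base

    def test_all_singletons_rejected(self):
        ds = FunctionalDataset(
            subjects=np.arange(5), t=np.linspace(0.1, 0.9, 5), y=np.zeros(5)
        )
        with pytest.raises(ValueError, match="off-diagonal"):
            fit_faces(ds)

    def test_covariance_evaluations(self, fitted, rng):
        fit, _ = fitted
        s = rng.uniform(0, 1, 7)
        t = rng.uniform(0, 1, 7)
        np.testing.assert_array_equal(fit.covariance(s, t), fit.covariance(t, s))
        grid = fit.covariance(s)
        point = np.array([fit.covariance([a], [b])[0] for a in s for b in s])
        np.testing.assert_allclose(grid.ravel(), point, atol=1e-12)

    def test_identity_theta_gives_basis_gram(self, fitted, rng):
        fit, _ = fitted
        from copy import deepcopy

        from facecov.basis import eval_basis

        probe = deepcopy(fit)
        probe.theta_ = np.eye(fit.n_basis)
        s = rng.uniform(0, 1, 5)
        B = eval_basis(probe.basis_, s)
        np.testing.assert_allclose(probe.covariance(s), B @ B.T, atol=1e-12)

    def test_sklearn_param_interface(self):
        est = FacesSmoother(n_basis=8)
        assert est.get_params()["n_basis"] == 8
        est.set_params(beta=0.1)
        assert est.beta == 0.1
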