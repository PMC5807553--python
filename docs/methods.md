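# Methods

## Model and estimator

Sparse functional data are modelled as `y_ij = f(t_ij) + u_i(t_ij) + eps_ij`
with times in the unit interval, a smooth population mean `f`, subject-level
zero-mean Gaussian processes `u_i` with covariance `C(s, t)`, and i.i.d.
Gaussian noise with variance `sigma2_eps`. All random terms are independent
across subjects and of each other.

The covariance is represented as a symmetric tensor-product spline
`H(s, t) = sum_{k,l} theta_kl B_k(s) B_l(t)` on a clamped, equally-knotted
marginal B-spline basis. Symmetry is imposed exactly by parameterizing with
the half-vectorization `theta = vech(Theta)` and the duplication matrix
`G_c` (`vec Theta = G_c theta`). Each within-subject pair of observations
`(j1 <= j2)` contributes one regression row
`[(b(t_j2) ⊗ b(t_j1))' G_c, delta_{j1 j2}]` against the residual product
`r_{ij1} r_{ij2}`; the 0/1 `delta` column absorbs `sigma2_eps` on the
diagonal (nugget) pairs, so the surface and the noise variance are estimated
jointly. The roughness penalty is `||Theta D||_F^2` with `D` the
second-order difference operator — the row penalty of bivariate P-splines,
which for symmetric coefficients coincides with the column penalty. As
`lambda -> inf` the surface becomes bilinear; the noise coordinate is never
penalized.

The nugget indicator is index-based, not time-based: two distinct
observations at the same time form an off-diagonal pair, because their noise
terms are independent and their product is unbiased for `C(t, t)` alone.

## Weights and the two-stage fit

The residual-product vector of one subject has, under Gaussianity, the
Isserlis covariance
`cov(C_{i j1 j2}, C_{i j3 j4}) = R_{13} R_{24} + R_{14} R_{23}` with
`R_{ab} = C(t_a, t_b) + delta_ab sigma2_eps`. Stage 1 fits with identity
weights; stage 2 plugs the stage-1 surface and noise estimate into the
Isserlis formula and uses the stabilized inverse
`W_i = [(1 - beta) cov + beta diag(cov)]^{-1}` with `beta = 0.05`.

Two implementation choices matter here:

* the plug-in surface is first made positive semidefinite by trimming
  negative eigenvalues on a 100-point grid and projecting back onto the
  coefficients (`Theta+ = M C+ M'`, `M = (B'B)^{-1} B'`). Without this the
  Isserlis matrix built from an indefinite plug-in can be genuinely
  indefinite and the blend non-invertible; with it the matrix is a true
  Gaussian covariance, hence PSD, and the blend is positive definite
  whenever the diagonal is positive. A tiny jitter (`1e-8` of the mean
  diagonal) remains as a fallback for borderline numerical cases;
* the plug-in noise is floored at `max(sigma2_stage1, 1e-6 * scale)` with
  `scale` the mean absolute stage-1 variance, so nugget rows keep positive
  variance even if stage 1 underestimates the noise.

The procedure is exactly two stages (no iteration), and the smoothing
parameter is re-selected in each stage. The returned `sigma2_` is clamped at
zero; the unclamped stage-1 value feeds the weights through the floor above.

## Fast smoothing-parameter selection

Leave-one-subject-out CV is approximated by iGCV, derived from the
block hat-matrix identity
`iCV = sum_i ||(I - S_ii)^{-1} (S_i C_hat - C_hat_i)||^2` via the expansion
`(I - S_ii')^{-1}(I - S_ii)^{-1} ≈ I + S_ii + S_ii'`. With the simultaneous
diagonalization `A'(X'WX)A = I`, `A'QA = diag(s)` the smoother becomes
`S = F D~ F' W` with `F = XA` and `D~ = (I + lambda diag(s))^{-1}`, and iGCV
collapses to a fixed expression in `d~ = diag(D~)` built from lambda-free
quantities (`f, f~, g, G-type matrices and per-subject Gram blocks`), costing
`O(n K^2)` per candidate lambda after one precomputation.

The cross term of this expression is computed as
`-2 d~' (G1 + G2) d~` with `G1 = sum_i (J_i f~') ⊙ L_i` and
`G2 = sum_i (f_i f~') ⊙ L~_i`. For identity weights `G1 = G2` and the term
equals the more compact `-4 d~' G1 d~`; under general weights only the
`G1 + G2` form agrees exactly with the direct smoother-matrix evaluation
(verified to ~1e-11 relative in the tests; the compact form drifts by ~1%).
Both forms have identical cost and lambda-free precomputation.

The lambda grid is 100 log-spaced points spanning `1e-8..1e8` times the
scale-free reference `tr(X'WX)/tr(Q)`. The argmin is taken over the grid
with near-ties (score differences below `1e-12 * ||C_hat||^2`, i.e. numerical
noise on a flat profile) resolved towards the larger lambda, so exactly
bilinear truths select maximal smoothing. Gram matrices receive a ridge of
`1e-10 * tr/K` before factorization.

The same subject-block CV identity (with `W = I`) selects the mean
smoothing parameter. The mean uses the same basis size and degree as the
covariance (c = 10, cubic) by default — one coherent smoothness family for
both levels; `mean="zero"` and `mean="known"` bypass mean estimation, which
is useful in simulations to isolate covariance error.

## fPCA and curve prediction

Eigenpairs of the covariance operator are approximated by Nyström: evaluate
on `g` midpoints of [0, 1] (default `g = 100`), eigendecompose the kernel
matrix scaled by `1/g`, rescale eigenvectors by `sqrt(g)` to be
L2-orthonormal, and trim negative eigenvalues to zero. The midpoint rule
converges at `O(g^-2)`; the top Matérn eigenvalue moves by under `1e-6`
between `g = 500` and `g = 1000`.

Subject curves are predicted by the Gaussian conditional expectation
evaluated through the spline kernel,
`x_hat = (H^n Theta H^o') V^{-1} (y - f^o) + f^n` with
`V = H^o Theta H^o' + sigma2 I`, avoiding eigenfunction evaluation at new
time points. The penalized `Theta` may be indefinite; prediction uses the
PSD surrogate described above (cached per fit), so predictive variances are
non-negative. The conditional covariance carries `sigma2` at the new points,
i.e. the 95% band (Gaussian multiplier 1.96) is a prediction interval for a
new noisy observation; its width shrinks to zero at observed points as
`sigma2 -> 0`.

Because the Matérn kernel and its reported operator spectrum pin down the
parameterization, `matern_cov` uses the classical Handcock–Stein form
`(d/phi)^nu K_nu(d/phi) / (2^(nu-1) Gamma(nu))`; the frequently seen
`sqrt(2 nu) d / phi` variant differs only by rescaling `phi` at `nu = 1` and
does not reproduce the spectrum 0.209/0.179 at range 0.07.

## Synthetic data: what it emulates and what it does not

The generator draws per-subject counts uniformly from {3..7} (mean 5) or
{5..15} (mean 10), times i.i.d. uniform on [0, 1], mean `5 sin(2 pi t)`,
and either a rank-3 trigonometric covariance (eigenvalues 1, 0.5, 0.25,
sampled through its Karhunen–Loeve scores) or a Matérn(0.07, 1) process
(sampled by Cholesky at the drawn times, jitter 1e-10). The noise variance
follows the trace rule `sigma2 = (1/SNR) int C(t, t) dt`: 0.875 (case 1)
and 0.5 (case 2) at SNR = 2. The double-integral variant
`(1/SNR) ∬ C ds dt` is not usable here — it is exactly zero for case 1
because every eigenfunction integrates to zero — so the trace convention is
the package's declared definition of signal level.

These are idealized conditions: Gaussian processes and noise, exactly
uniform design, no covariates, no missingness mechanism, a mean in the
spline space. Passing tests show correctness of the estimator and its
selectors under the stated model, not robustness to heavy tails, informative
observation times, or non-stationary noise.

## Evaluation criteria and problem sizes

Per replicate the harness computes: covariance ISE by midpoint quadrature on
a 100-point grid; sign-invariant eigenfunction ISEs
`min(∫(psi - psi_hat)^2, ∫(psi + psi_hat)^2) ∈ [0, 2]` and squared
eigenvalue errors for the top 3 components (from the `g = 100`
eigensystem of each fit); and curve-prediction ISE, defined as the mean over
200 freshly drawn test subjects of the trapezoid-rule integral of
`(X_hat - X)^2` on a 101-point grid, with the median over replicates
reported. Replication summaries are medians and IQRs.

The packaged test suite runs the replication studies at 20–50 replicates
(25 for the largest `n = 400` design) rather than several hundred — the
medians are stable at that size and the whole suite stays in the minutes
range on a single core. Monte-Carlo moment checks use 2e6 Gaussian draws
with 3-standard-error acceptance bands.

## Known limitations

* No likelihood/REML selection of the smoothing parameter; grid iGCV only.
* `Theta` itself is not constrained PSD; positivity is restored only for
  fPCA/prediction via grid trimming, so extreme small-sample fits can have
  mildly negative variance estimates on the raw surface.
* The mean model offers no covariate adjustment and no extrapolation
  outside [0, 1].
* Serialization covers P-spline and zero means only; arbitrary user-supplied
  mean callables cannot be archived.
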