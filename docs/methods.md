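# Methods

This note documents the statistical models implemented in `funbayes`, the
numerical and design choices behind them, what the synthetic-data
generators emulate, and known limitations.

## Models

### Scalar-on-function regression (SoFR)

For subject $i$ with outcome $Y_i$, scalar covariates $Z_i$, and a
functional covariate $W_i(t)$ observed on a shared grid
$t_1,\dots,t_M \subset [0,1]$, the linear predictor is

$$\eta_i = \eta_0 + \int_0^1 W_i(t)\,\beta(t)\,dt + Z_i^\top\gamma ,$$

with $Y_i$ Gaussian (dispersion $\sigma$) or Bernoulli with a logit link.
The coefficient is expanded in $K$ spline basis functions,
$\beta(t)=\sum_k b_k \psi_k(t)$, and the integral is approximated by a
Riemann sum with weights $L_m = t_{m+1}-t_m$ (the last weight replicated;
on the equispaced midpoint grid used by the simulations this is exactly
$1/M$). Smoothness is induced by the curvature penalty
$\int \beta''(t)^2\,dt = b^\top S b$ with
$S=\int \psi''(t)\,\psi''(t)^\top dt$, equivalently a prior
$p(b) \propto \exp(-b^\top S b / 2\sigma_b^2)$.

**Spectral reparametrization.** With $S = U V U^\top$ and
$\tilde b = \tilde V^{1/2} U^\top b$ (positive eigenvalues on the first
$K_0$ diagonal entries of $\tilde V$, positive scaling constants on the
null space), the prior becomes i.i.d. normal on the first $K_0$
transformed coordinates and flat on the rest, and the design transforms
as $\tilde X = \tilde V^{-1/2} U^\top X$ so fitted values are unchanged.
The null-space scaling constants are set from the squared Frobenius norm
of the design divided by its column count; the posterior is invariant to
this choice (the prior is flat in those directions) — it only affects
sampler conditioning, and the constants are recorded in the
`ReparamDesign` for audit. Eigenvalues are sorted descending and
eigenvector signs fixed (leading entry positive) for reproducibility.

### Functional Cox regression

Follow-up time $Y_i=\min(T_i, C_i)$ with right-censoring indicator
$\delta_i$ (**$\delta_i=0$ marks an observed event**, $\delta_i=1$
censoring; the CLI converts the conventional event=1 coding only under an
explicit flag). The hazard is $h_i(t) = h_0(t)\exp(\eta_i)$ with the
baseline modeled on an M-spline basis, $h_0(t)=\sum_l c_l M_l(t)$, whose
running integrals (I-splines) give the cumulative baseline
$H_0(t)=\sum_l c_l I_l(t)$. The full log likelihood is

$$\sum_i (1-\delta_i)\{\log h_0(y_i) + \eta_i\} - H_0(y_i) e^{\eta_i}.$$

Because $(a c,\ \eta_0 - \log a)$ gives the same hazard for any $a>0$,
the weights are constrained to the simplex with a flat Dirichlet prior.
Defaults: degree 3, $L=5$ basis functions, boundary knots at
$(0.99\,\min y,\ 1.01\,\max y)$, interior knots at quantiles of the
observed times. A subject's time is documented as censored exactly when
the censoring time precedes the event time; the inequality printed in
some accounts of this convention ("censored if $Y_i < T_i$") cannot hold
as written, since $Y_i=\min(T_i,C_i)\le T_i$, and is read here as
$C_i < T_i$.

### Joint FPCA + regression

When curves are noisy, regressing on the observed $W_i(t)$ attenuates the
coefficient and understates uncertainty. The joint model regresses on the
latent process: $W_i(t)=\sum_j \xi_{ij}\phi_j(t)+\epsilon_i(t)$ with
$\epsilon_i \sim N(0,\sigma_\epsilon^2)$ white noise, and

$$\eta_i = \eta_0 + \xi_i^\top X \, b + Z_i^\top \gamma, \qquad
X_{jk} = \int_0^1 \phi_j(t)\,\psi_k(t)\,dt,$$

with the same spectral reparametrization applied to $X$. Eigenfunctions
$\phi_j$ come from a frequentist FPCA of the observed curves and are held
fixed; the scores $\xi_{ij}$ are sampled jointly with the regression.

**Score prior.** Two forms are implemented. `score_prior="paper"` centers
the prior at the frequentist score estimates,
$\xi_{ij} \sim N(\hat\xi_{ij}, \lambda_j)$, using $\lambda_j$ both as the
prior variance and as an eigenvalue with its own IG hyperprior. In
practice this is degenerate: $\lambda_j$ is then identified only through
the deviations $\xi-\hat\xi$, its posterior collapses toward zero, the
scores freeze at the plug-in estimates, and the uncertainty propagation
that motivates the joint model is lost (we observed $\lambda_j$ posterior
means near 0.01 against generating eigenvalues of order 4, with severe
undercoverage). The pipeline entry point `fit_joint` therefore defaults
to the zero-centered Karhunen–Loève form, $\xi_{ij} \sim N(0,\lambda_j)$,
under which $\lambda_j$ is the process eigenvalue, identified by the
curves themselves. The printed form remains available behind the flag and
is exercised at the density level in the tests.

### Function-on-scalar regression (FoSR)

$Y_i(t) = \sum_p X_{ip}\beta_p(t) + e_i(t)$ with residual process
$e_i(t)=\sum_j \xi_{ij}\phi_j(t) + \epsilon_i(t)$. Each coefficient curve
$\beta_p(t)$ has its own smoothing variance $\sigma_p^2$ through the
untransformed-basis prior
$p(b_p)\propto \exp(-b_p^\top S b_p/2\sigma_p^2)$ (no spectral
reparametrization here: the original basis keeps the coefficients
directly interpretable). Residual eigenfunctions are obtained by FPCA of
pointwise least-squares residuals.

## Functional principal component analysis

Mean: pointwise (or fixed at zero for the simulation designs).
Covariance: sample covariance with the diagonal removed, smoothed by a
two-dimensional local linear smoother with a Gaussian product kernel
(default bandwidth 0.1 on the unit domain; separability reduces the
smoother to a handful of $M\times M$ matrix products). Noise variance:
average gap between raw and smoothed diagonals, truncated at zero (zero
when smoothing is disabled). Eigenanalysis is performed in the quadrature
metric so eigenfunctions satisfy $\Phi^\top \mathrm{diag}(L_m)\Phi = I$;
signs are fixed by non-negative grid sums. Scores are conditional
expectations
$\hat\xi_i = \Lambda\Phi^\top \mathrm{diag}(L)\,
(\Phi\Lambda\Phi^\top \mathrm{diag}(L) + \sigma_\epsilon^2 I)^{-1}
(W_i-\mu)$, reducing to the weighted projection as
$\sigma_\epsilon^2 \to 0$. The number of components is chosen by a
proportion-of-variance threshold (default 0.99) unless fixed; the
simulation harness fixes $J=4$.

## Priors

Penalized coefficients $\tilde b_r \sim N(0, \sigma_b^2 I)$; every
variance component ($\sigma_b^2$, $\sigma_\epsilon^2$, $\lambda_j$,
$\sigma_p^2$) has an IG(0.001, 0.001) prior; the Gaussian dispersion is
parameterized as a standard deviation with a flat positive prior; simplex
hazard weights have a flat Dirichlet; intercepts, null-space directions,
and scalar coefficients are improper-flat by default, with an optional
proper $N(0, \text{flat\_sd}^2)$ via a flag.

## Posterior computation

The sampler is a No-U-Turn sampler (recursive tree doubling with a slice
variable, dual-averaging step-size adaptation toward 0.8 acceptance, and
a diagonal mass matrix estimated from an intermediate warmup window) on
the unconstrained scale: log transforms for variances and a
stick-breaking transform for the simplex, with analytic gradients for
every model (finite-difference-verified in the test suite). Production
defaults are 3 chains of 15,000 iterations with 5,000 warmup; the
simulation harnesses use single short chains (see "Problem sizes").

Three sampler-side reparametrizations address geometry; none changes the
posterior:

* **Coefficient whitening** (SoFR, Cox, joint): the regression block is
  sampled as $\theta = T u$ with $T^{-\top}T^{-1}$ an approximation of the
  likelihood curvature (a fixed linear map computed once), decorrelating
  directions that a diagonal mass matrix cannot.
* **Gaussian SoFR marginalization**: conditional on
  $(\sigma_b^2,\sigma^2)$ the coefficients are exactly Gaussian, so NUTS
  runs on the two log-variances only and coefficients are drawn from
  their exact conditional per retained draw. This removes the
  smoothing-variance funnel, in which short chains can otherwise get
  trapped at $\sigma_b^2 \approx 0$ (oversmoothed fits with overconfident
  bands).
* **FoSR score marginalization**: for orthogonal eigenfunction columns
  the residual-process covariance has closed-form eigenstructure, so the
  scores are integrated out analytically (the marginal density depends on
  the data only through fixed cross-moments, making an evaluation
  $O(K^2J)$ regardless of $n$) and redrawn exactly per retained draw.
  The explicit-score density is retained as the reference implementation
  and as the fallback for non-orthogonal eigenfunctions; a test verifies
  both routes target the same posterior.

Divergent-transition fractions above 10% are surfaced as a warning;
non-finite initializations are retried with jitter. Diagnostics report
arviz's rank-normalized split-$\hat R$ and bulk ESS; note the
rank-normalized statistic is bounded (≈1.8 for two disjoint chains of 400
draws) rather than diverging to infinity.

## Credible bands

From the $Q\times M$ matrix of coefficient-curve draws: posterior mean
$\hat\beta(t)$ and sd $\hat S(t)$ columnwise; the simultaneous (CMA) band
is $\hat\beta(t) \pm q_d \hat S(t)$ where $q_d$ is the empirical
$(1-\alpha)$ quantile (type-7 interpolation) of the max statistic
$d_q = \max_t |\beta_q(t)-\hat\beta(t)|/\hat S(t)$. Pointwise intervals
default to the per-$t$ quantile of the same standardized deviation, which
guarantees they nest inside the CMA band; equal-tailed percentile
intervals are available by flag. Grid points with (numerically) zero
posterior sd are excluded from the max with a warning and the band
collapses to the mean there.

## Synthetic data

Curves are built from $J=4$ orthonormal eigenfunctions with eigenvalues
$(4, 2, 1, 0.5)$ plus optional white noise (sd 0, 5, or 10), observed at
$M=50$ equispaced (midpoint) points of $[0,1]$; the packaged
eigenfunctions are the constant-free Fourier pairs
$\sqrt2\sin 2\pi t, \sqrt2\cos 2\pi t, \sqrt2\sin 4\pi t,
\sqrt2\cos 4\pi t$, which are exactly orthonormal under the quadrature
weights on this grid. A loader accepts externally estimated
eigenfunctions (e.g., from an accelerometry cohort) for closer parity
with any particular application. The true coefficient is the quadratic
$\beta(t) = (0.084 - (t-0.5)^2)\tau$ with signal strength $\tau$.
Outcomes: Gaussian with sd 1.5 around
$\eta_i = \frac1M\sum_m W_i(t_m)\beta(t_m)$; Bernoulli through the logit;
survival times by numerical inversion of the cumulative baseline hazard
(default $h_0(t)=1.5\sqrt t$, a Weibull-type shape; draws beyond the
tabulated range become administratively censored at end of study), with
censoring times drawn as a random permutation of the simulated event
times (realized censoring fraction ≈ 50%, reported per run rather than
tuned). FoSR responses are $Y_i(t) = X_i\beta(t) + W_i(t) +
\epsilon_i(t)$ with $X_i \sim N(20, 10)$ (the "N(20,10)" of the design is
read as mean 20, **variance** 10; configurable) and noise variance 5.

**What the generator does not emulate.** Real accelerometry-derived
eigenfunctions and baseline hazards are not reproduced — the packaged
Fourier set preserves the statistical structure (orthonormal components
with decreasing variances), not the numerical values, so absolute
integrated-error magnitudes are comparable-order rather than identical,
while coverage and ordering properties are preserved. Two of the four
packaged eigenfunctions are exactly orthogonal to the quadratic
coefficient, so they carry no outcome signal; the coefficient's
projection onto the component span leaves a residual of ≈1.7% relative
integrated squared error, a floor far below the estimation error at the
sample sizes studied.

**Identifiability under this generator.** The packaged eigenfunctions
integrate to zero, so simulated curves carry no information about the
constant component of $\beta(t)$; with a flat prior on the penalty null
space that direction would be improper. The simulation and evaluation
harnesses therefore fit with the sum-to-zero constraint absorbed into the
basis (`center=True`, reducing $K=10$ to 9 functions), the same device
used by standard mixed-model smoothing software. The true coefficient's
integral is $6.7\times10^{-4}\tau$, so the centered span loses
essentially nothing. The library default leaves the constraint off, since
real curves generically have nonzero integrals. The FoSR fit uses the
uncentered basis (the response is observed directly) and regresses on the
single scalar predictor without an intercept curve, matching the
generating model — with an added intercept the coefficient is identified
only through deviations of $X$ from its mean, a many-fold harder problem
with qualitatively larger integrated errors.

## Evaluation metrics

RISE $= \int(\beta-\hat\beta)^2 dt / \int\beta^2 dt$ by quadrature;
pointwise coverage = percent of grid points whose pointwise band covers
the truth (CMA coverage reported alongside; coverage pools grid points
within a replicate and averages over replicates). The prediction metric
is scored on a 500-subject holdout as mean squared error on the
linear-predictor scale (Gaussian, Cox — Cox predictors are centered
first, since the intercept scale is absorbed by the baseline hazard) or
the probability scale (Bernoulli); scoring on these scales keeps the
metric free of irreducible outcome noise. Replicate studies derive
per-replicate seeds from a master seed by counter; reports are pure
functions of the stored per-replicate tables.

## Problem sizes

Replicate studies in the test suite and acceptance script run at desk
scale: single chains of 450–1,200 iterations (roughly one-third warmup),
8–20 replicates per cell for trend checks and 50 for coverage cells, with
sample sizes 100–500. Monte-Carlo standard errors are reported with every
cell. Trend comparisons across cells use common random numbers (shared
replicate seeds) to reduce comparison variance. Full-scale settings
(3 × 15,000-iteration chains, 500 replicates) are available through the
same interfaces.

## Known limitations

* Irregular per-subject grids are supported only through the FPCA/joint
  route; the direct regression path requires complete curves on a common
  grid.
* Multilevel FPCA, time-varying Cox effects, stratification, left
  truncation, and variational inference are out of scope.
* The covariance smoother uses a fixed default bandwidth, not a data-
  driven one; for unusual grid densities the bandwidth should be set
  explicitly.
* The "paper"-form joint score prior is provided for fidelity but is
  statistically degenerate (see above); the zero-centered default is
  recommended.
* Exact numeric parity with any particular reference software's interior
  knot placement or null-space scaling constants is not claimed; both
  affect only parametrization, not the posterior.
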