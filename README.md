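# funbayes

Bayesian functional regression with penalized splines — for
biostatisticians and epidemiologists analyzing densely observed
functional covariates or responses (accelerometry profiles, glucose
traces, EEG power curves) alongside scalar covariates and scalar, binary,
or time-to-event outcomes.

Four model families share one backbone:

* **Scalar-on-function regression (SoFR)** — Gaussian or logistic outcome
  with linear predictor
  `η_i = η₀ + ∫ W_i(t) β(t) dt + Z_iᵀγ`;
* **Functional Cox regression** — proportional hazards
  `h_i(t) = h₀(t) exp(η_i)` with the baseline hazard on an M-spline basis
  (simplex weights; I-splines give the cumulative hazard in closed form);
* **Joint FPCA + regression** — noisy curves are modeled as latent score
  processes `W_i(t) = Σ_j ξ_ij φ_j(t) + ε_i(t)` and the regression runs
  on the latent scores, propagating score uncertainty into the outcome
  model;
* **Function-on-scalar regression (FoSR)** — functional response with one
  smooth coefficient curve per scalar predictor and a principal-component
  residual process.

The coefficient `β(t) = Σ_k b_k ψ_k(t)` carries the Wahba–O'Sullivan
curvature penalty `∫ β″(t)² dt = bᵀS b`, treated as a normal prior and
diagonalized by the spectral reparametrization `b̃ = Ṽ^{1/2} Uᵀ b`
(i.i.d. normal prior on the penalized coordinates, flat on the null
space). Posterior inference uses a built-in No-U-Turn sampler with
analytic gradients; summaries include pointwise credible intervals and
simultaneous CMA (correlation-and-multiplicity-adjusted) bands built from
the posterior of the maximum standardized deviation. A synthetic-data
module generates every simulation design used by the tests, so the whole
package is exercisable without any external data.

See `docs/methods.md` for the models, priors, numerical choices, and what
the generators do and do not emulate.

## Worked example

```python
import funbayes as fb
from funbayes.bayes_models import SamplerConfig

# simulate: n=300 subjects, curves from 4 orthonormal components with
# eigenvalues (4,2,1,0.5), quadratic signal beta(t) = (0.084-(t-.5)^2)*5,
# Gaussian outcome with sd 1.5
data = fb.simulate_sofr(fb.DGPConfig(n=300, tau=5, seed=7))

# basis with the sum-to-zero constraint absorbed (these synthetic curves
# integrate to zero, so the constant direction must be constrained)
basis = fb.build_penalized_basis(data.grid, K=10, center=True)

fit = fb.fit_sofr(data, basis, family="gaussian",
                  sampler=SamplerConfig(chains=2, iterations=2000,
                                        warmup=700, seed=1))

beta_draws = fb.reconstruct_beta(fit.draws, fit.rd, fit.basis)
bands = fb.cma_band(beta_draws, grid=data.grid)
beta_true = fb.true_beta(data.grid, 5.0)
print(f"RISE  = {fb.rise(beta_true, bands.beta_hat):.3f}")
print(f"pointwise 95% coverage = "
      f"{fb.pointwise_coverage(bands, beta_true):.1f}%")
print(f"CMA multiplier q_d = {bands.q_d:.2f}")
```

Output:

```
RISE  = 0.043
pointwise 95% coverage = 100.0%
CMA multiplier q_d = 3.32
```

The relative integrated squared error (`∫(β−β̂)²/∫β²`) of 0.043 says the
fitted coefficient captures ~96% of the signal's integrated square; the
pointwise bands cover the true curve everywhere on this replicate; and
the simultaneous band is q_d/1.96 ≈ 1.7× wider than a pointwise normal
interval, the price of covering the whole curve at once. Convergence for
this run: split-R̂ ≤ 1.01, bulk ESS ≥ 500 for all parameters
(`funbayes.diagnostics(fit.draws)`).

## Command line

```bash
funbayes simulate --family gaussian --n 200 --tau 2 --seed 1 --out data/
funbayes fit --family gaussian --w-csv data/W.csv --grid-csv data/grid.csv \
    --outcome-csv data/outcome.csv --k 10 --chains 3 --iter 15000 \
    --warmup 5000 --seed 1 --out results/
funbayes study --families gaussian --ns 100,200 --taus 1,2 \
    --replicates 10 --out study/
```

`fit` writes a coefficient summary (`summary.csv`: mean, sd, pointwise
and CMA bands per grid point), scalar-coefficient tables, tidy draws,
diagnostics, a band plot, and a manifest (config + seed + versions) from
which the run can be regenerated. Survival outcomes require an explicit
`--censor-coding {paper,event1}` choice because the modeling convention
(0 = event) is the reverse of the common event=1 coding.

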