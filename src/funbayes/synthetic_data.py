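"""Synthetic data generators for the simulation designs.

Functional covariates are built from J orthonormal eigenfunctions with
decreasing variances,

    W_i(t_m) = sum_j xi_ij phi_j(t_m) + noise_sd * e_im,
    xi_ij ~ N(0, lambda_j),

on M equally spaced points of [0, 1]. The packaged eigenfunctions are the
constant-free Fourier pairs ``sqrt(2) sin(2 pi t), sqrt(2) cos(2 pi t),
sqrt(2) sin(4 pi t), sqrt(2) cos(4 pi t)`` with variances (4, 2, 1, 0.5);
on the midpoint grid used here they are exactly orthonormal under the
Riemann quadrature weights. Externally estimated eigenfunctions (for
example from an accelerometry cohort) can be supplied instead.

The functional coefficient is the quadratic ``beta(t) = (0.084 -
(t - 0.5)^2) * tau`` whose signal strength is controlled by ``tau``.
Outcomes are generated from the quadrature linear predictor
``eta_i = (1/M) sum_m W_i(t_m) beta(t_m)``:

* Gaussian with standard deviation 1.5, or Bernoulli with success
  probability ``logit^{-1}(eta_i)``;
* time-to-event via the inverse cumulative-hazard transform under a
  proportional-hazards model, with censoring times drawn as a random
  permutation of the simulated event times;
* function-on-scalar responses ``Y_i(t) = X_i beta(t) + W_i(t) + eps_i(t)``
  with a scalar predictor ``X_i ~ N(20, 10)`` (variance 10) and
  ``eps ~ N(0, 5)`` (variance 5).

All generators are deterministic given (config, seed): the seed feeds a
single Generator whose draw order is fixed, and the evaluation holdout set
(500 subjects by default) is produced within the same stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .functional_design import FunctionalDataset

__all__ = ["DGPConfig", "default_grid", "default_eigenfunctions",
           "true_beta", "simulate_sofr", "simulate_survival",
           "simulate_fosr", "FoSRData"]

DEFAULT_EIGENVALUES = (4.0, 2.0, 1.0, 0.5)


def default_grid(M: int = 50) -> np.ndarray:
    """Midpoint grid ``t_m = (2m - 1) / (2M)`` of M equispaced points."""
    return (2 * np.arange(1, M + 1) - 1) / (2 * M)


def default_eigenfunctions(grid, J: int = 4) -> np.ndarray:
    """Constant-free Fourier pairs, orthonormal in L2[0, 1]."""
    if J > 4:
        raise ValueError("the packaged set has 4 eigenfunctions")
    t = np.asarray(grid, dtype=float)
    funcs = [np.sqrt(2) * np.sin(2 * np.pi * t),
             np.sqrt(2) * np.cos(2 * np.pi * t),
             np.sqrt(2) * np.sin(4 * np.pi * t),
             np.sqrt(2) * np.cos(4 * np.pi * t)]
    return np.column_stack(funcs[:J])


@dataclass
class DGPConfig:
    """Study conditions for one simulated dataset."""

    n: int = 200
    M: int = 50
    tau: float = 1.0
    family: str = "gaussian"          # gaussian | bernoulli_logit | cox | fosr
    eigenvalues: tuple = DEFAULT_EIGENVALUES
    eigenfunctions: Optional[np.ndarray] = None   # M x J, else packaged set
    noise_sd: float = 0.0             # sd of white noise on observed W
    gaussian_sd: float = 1.5          # outcome sd, Gaussian family
    scalar_mean: float = 20.0         # FoSR scalar predictor mean
    scalar_var: float = 10.0          # FoSR scalar predictor variance
    fosr_eps_var: float = 5.0         # FoSR white-noise variance
    holdout: int = 500                # evaluation subjects for prediction
    seed: int = 0

    def grid(self) -> np.ndarray:
        return default_grid(self.M)

    def phi(self) -> np.ndarray:
        if self.eigenfunctions is not None:
            Phi = np.asarray(self.eigenfunctions, dtype=float)
            if Phi.shape[0] != self.M:
                raise ValueError("eigenfunctions must be on the M-point grid")
            return Phi[:, :len(self.eigenvalues)]
        return default_eigenfunctions(self.grid(), len(self.eigenvalues))


def true_beta(grid, tau: float) -> np.ndarray:
    """Quadratic signal ``(0.084 - (t - 0.5)^2) * tau``."""
    t = np.asarray(grid, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("grid must lie in [0, 1]")
    return (0.084 - (t - 0.5) ** 2) * tau


def _draw_curves(cfg: DGPConfig, n: int, rng) -> tuple:
    Phi = cfg.phi()
    lam = np.asarray(cfg.eigenvalues, dtype=float)
    xi = rng.standard_normal((n, lam.size)) * np.sqrt(lam)
    W = xi @ Phi.T
    if cfg.noise_sd > 0:
        W = W + cfg.noise_sd * rng.standard_normal(W.shape)
    return W, xi


def _eta(cfg: DGPConfig, W: np.ndarray) -> np.ndarray:
    beta = true_beta(cfg.grid(), cfg.tau)
    return W @ beta / cfg.M


def simulate_sofr(cfg: DGPConfig) -> FunctionalDataset:
    """Scalar-on-function dataset (Gaussian or Bernoulli outcome).

    The returned dataset carries ground truth in ``extra``: true linear
    predictors (``eta``), success probabilities for Bernoulli, the true
    coefficient curve, and a holdout FunctionalDataset for prediction
    scoring.
    """
    if cfg.family not in ("gaussian", "bernoulli_logit"):
        raise ValueError("simulate_sofr requires a GLM family")
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    out = []
    for size in (cfg.n, cfg.holdout):
        W, xi = _draw_curves(cfg, size, rng)
        eta = _eta(cfg, W)
        extra = {"eta": eta, "xi": xi,
                 "beta_true": true_beta(grid, cfg.tau), "config": cfg}
        if cfg.family == "gaussian":
            y = eta + cfg.gaussian_sd * rng.standard_normal(size)
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
            y = (rng.uniform(size=size) < p).astype(float)
            extra["prob"] = p
        out.append(FunctionalDataset(W=W, grid=grid, y=y, extra=extra))
    data, hold = out
    data.extra["holdout"] = hold
    return data


def _default_baseline(t):
    """Weibull-shaped default hazard ``h0(t) = 1.5 sqrt(t)``."""
    return 1.5 * np.sqrt(np.maximum(t, 0.0))


def simulate_survival(cfg: DGPConfig,
                      baseline: Optional[Callable] = None,
                      t_max: float = 5.0) -> FunctionalDataset:
    """Time-to-event dataset under a functional proportional-hazards model.

    Event times come from the inverse-transform relation ``T_i =
    H0^{-1}(-log U_i / exp(eta_i))`` with the cumulative baseline inverted
    numerically on a dense grid; draws beyond the tabulated range are set
    to the administrative end of study ``t_max`` and censored. Censoring
    times are a uniform random permutation of the simulated event times;
    the recorded indicator is 0 for an observed event and 1 for censoring.
    """
    rng = np.random.default_rng(cfg.seed)
    h0 = baseline if baseline is not None else _default_baseline
    tg = np.linspace(0.0, t_max, 4001)
    hv = np.asarray(h0(tg), dtype=float)
    if np.any(hv < 0):
        raise ValueError("baseline hazard must be non-negative")
    H = np.concatenate([[0.0], np.cumsum(0.5 * (hv[1:] + hv[:-1])
                                         * np.diff(tg))])
    grid = cfg.grid()

    def draw(size):
        W, xi = _draw_curves(cfg, size, rng)
        eta = _eta(cfg, W)
        u = rng.uniform(size=size)
        target = -np.log(u) / np.exp(eta)
        T = np.interp(target, H, tg, right=np.inf)
        admin = ~np.isfinite(T)
        T[admin] = t_max
        C = rng.permutation(T)
        y = np.minimum(T, C)
        censor = ((C < T) | admin).astype(float)  # 1 = censored
        y = np.maximum(y, 1e-6)  # guard: positive follow-up times
        extra = {"eta": eta, "xi": xi, "T": T, "C": C,
                 "beta_true": true_beta(grid, cfg.tau), "config": cfg}
        return FunctionalDataset(W=W, grid=grid, y=y, censor=censor,
                                 extra=extra)

    data = draw(cfg.n)
    data.extra["holdout"] = draw(cfg.holdout)
    return data


@dataclass
class FoSRData:
    """Function-on-scalar simulation output."""

    Y: np.ndarray                 # n x M functional response
    X: np.ndarray                 # n scalar predictor
    grid: np.ndarray
    beta_true: np.ndarray
    W: np.ndarray                 # random-effect process component
    config: DGPConfig = None


def simulate_fosr(cfg: DGPConfig) -> FoSRData:
    """Functional response driven by one scalar predictor.

    ``Y_i(t) = X_i beta(t) + W_i(t) + eps_i(t)`` with ``X_i ~ N(20, 10)``
    (variance 10) and white noise of variance 5 by default.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    W, _ = _draw_curves(cfg, cfg.n, rng)
    X = cfg.scalar_mean + np.sqrt(cfg.scalar_var) * rng.standard_normal(cfg.n)
    beta = true_beta(grid, cfg.tau)
    eps = np.sqrt(cfg.fosr_eps_var) * rng.standard_normal((cfg.n, cfg.M))
    Y = X[:, None] * beta[None, :] + W + eps
    return FoSRData(Y=Y, X=X, grid=grid, beta_true=beta, W=W, config=cfg)
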