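"""Posterior summaries of functional coefficients.

Coefficient draws on the transformed scale are mapped back to the spline
basis and evaluated on the grid, giving a Q x M matrix of functional
coefficient draws. From it we form the posterior mean curve, pointwise
credible intervals, and the simultaneous CMA (correlation and multiplicity
adjusted) band built from the posterior distribution of the maximum
standardized deviation

    d_q = max_t |beta_q(t) - beta_hat(t)| / S_hat(t),

whose empirical (1 - alpha) quantile q_d scales the band
``beta_hat(t) +/- q_d * S_hat(t)``. By construction at least a (1 - alpha)
fraction of posterior curves lies entirely inside the CMA band, and the CMA
band contains the pointwise one everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bases import PenalizedBasis
from .reparam import ReparamDesign, back_transform

__all__ = ["FunctionalCoefficientSummary", "reconstruct_beta",
           "reconstruct_beta_direct", "cma_band",
           "scalar_coefficient_table", "diagnostics", "plot_bands"]


@dataclass
class FunctionalCoefficientSummary:
    grid: np.ndarray
    beta_hat: np.ndarray
    sd_hat: np.ndarray
    pointwise_lo: np.ndarray
    pointwise_hi: np.ndarray
    cma_lo: np.ndarray
    cma_hi: np.ndarray
    alpha: float
    q_d: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.grid, "beta_hat": self.beta_hat, "sd": self.sd_hat,
            "pw_lo": self.pointwise_lo, "pw_hi": self.pointwise_hi,
            "cma_lo": self.cma_lo, "cma_hi": self.cma_hi})

    def contains(self, curve) -> np.ndarray:
        """Pointwise indicator that the pointwise band covers ``curve``."""
        curve = np.asarray(curve)
        return (self.pointwise_lo <= curve) & (curve <= self.pointwise_hi)

    def cma_contains(self, curve) -> np.ndarray:
        curve = np.asarray(curve)
        return (self.cma_lo <= curve) & (curve <= self.cma_hi)


def reconstruct_beta(draws, rd: ReparamDesign,
                     basis: PenalizedBasis) -> np.ndarray:
    """Q x M matrix of functional-coefficient draws.

    Accepts a PosteriorDraws (with ``br``/``bf`` blocks) or a (Q, K) array
    of transformed coefficients; each draw is mapped back to the original
    spline coefficients and evaluated on the basis grid.
    """
    if hasattr(draws, "stacked"):
        br = draws.stacked("br")
        bf = draws.stacked("bf")
        bt = np.hstack([br, bf]) if bf.size else br
    else:
        bt = np.atleast_2d(np.asarray(draws, dtype=float))
    if bt.shape[1] != rd.K:
        raise ValueError("coefficient draws do not match the basis dimension")
    b = back_transform(bt, rd)
    return b @ basis.Psi.T


def reconstruct_beta_direct(b_draws, basis: PenalizedBasis) -> np.ndarray:
    """Q x M coefficient draws from original-basis coefficients (used by
    the direct-penalty variant and function-on-scalar fits)."""
    b = np.atleast_2d(np.asarray(b_draws, dtype=float))
    return b @ basis.Psi.T


def cma_band(beta_draws, alpha: float = 0.05, grid=None,
             pointwise: str = "standardized") -> FunctionalCoefficientSummary:
    """Pointwise and simultaneous credible bands from coefficient draws.

    ``pointwise='standardized'`` (default) builds the pointwise interval
    from the per-t quantile of the standardized absolute deviation, which
    guarantees it nests inside the CMA band; ``pointwise='quantile'`` uses
    equal-tailed percentiles instead.

    Grid points with zero posterior standard deviation are excluded from
    the max statistic (the band collapses to the mean there).
    """
    B = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    Q, M = B.shape
    if grid is None:
        grid = np.arange(M, dtype=float)
    beta_hat = B.mean(axis=0)
    sd_hat = B.std(axis=0, ddof=1) if Q > 1 else np.zeros(M)
    # a coordinate whose draws are constant to rounding error is degenerate
    ok = sd_hat > 1e-12 * max(float(sd_hat.max(initial=0.0)), 1.0)
    if not np.all(ok):
        import warnings
        warnings.warn("degenerate coordinates with zero posterior sd "
                      "excluded from the simultaneous max statistic")
    dev = np.abs(B - beta_hat)
    std_dev = np.zeros_like(dev)
    std_dev[:, ok] = dev[:, ok] / sd_hat[ok]

    d_q = std_dev[:, ok].max(axis=1) if ok.any() else np.zeros(Q)
    q_d = float(np.quantile(d_q, 1 - alpha)) if ok.any() else 0.0

    if pointwise == "standardized":
        q_pw = np.quantile(std_dev, 1 - alpha, axis=0)
        pw_lo = beta_hat - q_pw * sd_hat
        pw_hi = beta_hat + q_pw * sd_hat
    elif pointwise == "quantile":
        pw_lo = np.quantile(B, alpha / 2, axis=0)
        pw_hi = np.quantile(B, 1 - alpha / 2, axis=0)
    else:
        raise ValueError("pointwise must be 'standardized' or 'quantile'")

    return FunctionalCoefficientSummary(
        grid=np.asarray(grid, dtype=float), beta_hat=beta_hat, sd_hat=sd_hat,
        pointwise_lo=pw_lo, pointwise_hi=pw_hi,
        cma_lo=beta_hat - q_d * sd_hat, cma_hi=beta_hat + q_d * sd_hat,
        alpha=alpha, q_d=q_d)


def scalar_coefficient_table(draws, names=None, level: float = 0.95):
    """Posterior mean and central credible interval per scalar covariate.

    Returns a DataFrame with columns (name, estimate, lo, hi, formatted),
    the last mirroring the conventional "estimate (lo, hi)" layout.
    """
    g = draws.stacked("gamma") if hasattr(draws, "stacked") else \
        np.atleast_2d(np.asarray(draws, dtype=float))
    if g.ndim == 1:
        g = g[:, None]
    p = g.shape[1]
    names = names if names is not None else [f"z{j}" for j in range(p)]
    a = (1 - level) / 2
    rows = []
    for j in range(p):
        est = g[:, j].mean()
        lo, hi = np.quantile(g[:, j], [a, 1 - a])
        rows.append({"name": names[j], "estimate": est, "lo": lo, "hi": hi,
                     "formatted": f"{est:.3f} ({lo:.3f}, {hi:.3f})"})
    return pd.DataFrame(rows)


def diagnostics(draws) -> pd.DataFrame:
    """Split-R-hat, bulk ESS, and divergence counts per parameter.

    With a single chain, R-hat is omitted (reported as NaN) with a notice.
    """
    import arviz as az

    rows = []
    single = draws.n_chains < 2
    if single:
        import warnings
        warnings.warn("single chain: split R-hat not computed")
    for name, arr in draws.params.items():
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for j in range(flat.shape[2]):
            label = name if flat.shape[2] == 1 else f"{name}[{j}]"
            chains = flat[:, :, j]
            ess = float(np.asarray(
                az.ess(az.convert_to_dataset(chains[..., None]))
                .to_array().values).ravel()[0])
            rhat = np.nan if single else float(np.asarray(
                az.rhat(az.convert_to_dataset(chains[..., None]))
                .to_array().values).ravel()[0])
            rows.append({"parameter": label, "rhat": rhat, "ess_bulk": ess})
    out = pd.DataFrame(rows)
    out.attrs["divergences"] = int(draws.divergences.sum())
    return out


def trace_data(draws, name) -> pd.DataFrame:
    """Long-format (chain, iteration, value) table for traceplots."""
    arr = draws.params[name].reshape(draws.params[name].shape[0],
                                     draws.params[name].shape[1], -1)[:, :, 0]
    frames = [pd.DataFrame({"chain": c, "iteration": np.arange(arr.shape[1]),
                            "value": arr[c]}) for c in range(arr.shape[0])]
    return pd.concat(frames, ignore_index=True)


def plot_bands(summary: FunctionalCoefficientSummary, path=None, ax=None,
               truth=None):
    """Mean curve with shaded pointwise (darker) and CMA (lighter) bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = summary.grid
    ax.fill_between(t, summary.cma_lo, summary.cma_hi, color="0.85",
                    label=f"CMA {100 * (1 - summary.alpha):.0f}% band")
    ax.fill_between(t, summary.pointwise_lo, summary.pointwise_hi,
                    color="0.65", label="pointwise band")
    ax.plot(t, summary.beta_hat, "k-", label="posterior mean")
    if truth is not None:
        ax.plot(t, truth, "r--", label="truth")
    ax.set_xlabel("t")
    ax.set_ylabel(r"$\beta(t)$")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
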