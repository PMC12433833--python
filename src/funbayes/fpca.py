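"""Functional principal component analysis on a common grid.

Estimates the mean function, a smoothed covariance surface, eigenfunctions
and eigenvalues, the white-noise variance, and conditional-expectation
scores. The decomposition underlies the joint regression models, which
re-estimate the score distribution but center their score priors at the
estimates produced here.

The covariance is estimated as the sample covariance with its diagonal
removed (the diagonal carries the noise variance) and smoothed by a
two-dimensional local linear smoother with a Gaussian kernel; the noise
variance is the average gap between the raw and smoothed diagonals,
truncated at zero. Smoothing can be switched off for noiseless data, in
which case the noise variance is reported as zero.

Eigenfunctions are orthonormal with respect to the quadrature weights of
the grid: ``Phi^T diag(L_m) Phi = I``. Signs are fixed so each
eigenfunction has a non-negative sum over the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .functional_design import FunctionalDataset, quadrature_weights

__all__ = ["FPCAResult", "fpca_fit", "predict_scores"]


@dataclass
class FPCAResult:
    mu: np.ndarray            # (M,) mean function
    Phi: np.ndarray           # (M, J) eigenfunctions
    lam: np.ndarray           # (J,) eigenvalues, non-increasing
    sigma2_eps: float         # noise variance >= 0
    scores: np.ndarray        # (n, J) conditional-expectation scores
    pve: float                # proportion of variance explained by the J comps
    grid: np.ndarray = None
    lweights: np.ndarray = None

    @property
    def J(self) -> int:
        return self.Phi.shape[1]

    def to_csv_bundle(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "mu.csv", self.mu, delimiter=",")
        np.savetxt(directory / "phi.csv", self.Phi, delimiter=",")
        np.savetxt(directory / "lambda.csv", self.lam, delimiter=",")
        np.savetxt(directory / "scores.csv", self.scores, delimiter=",")


def fpca_fit(data, J=None, pve: float = 0.99, smooth: bool = True,
             bandwidth: float = 0.1, center: bool = True) -> FPCAResult:
    """Fit FPCA to dense curves on a common grid.

    Parameters
    ----------
    data : FunctionalDataset or (n, M) array
        Observed curves; an array is interpreted on an equispaced grid.
    J : int, optional
        Number of components. When omitted, the smallest J reaching the
        ``pve`` threshold is used.
    pve : float
        Proportion-of-variance-explained threshold for automatic J.
    smooth : bool
        Smooth the off-diagonal covariance and estimate the noise variance
        from the diagonal gap. Disable for noiseless data.
    bandwidth : float
        Gaussian-kernel bandwidth of the local linear covariance smoother,
        on the scale of the (unit) domain.
    center : bool
        Subtract the pointwise mean. When False the mean is taken as zero
        (the convention of the simulation designs).
    """
    if isinstance(data, FunctionalDataset):
        W, grid, w = data.W, data.grid, data.lweights
    else:
        W = np.asarray(data, dtype=float)
        grid = np.linspace(0, 1, W.shape[1])
        w = quadrature_weights(grid)
    n, M = W.shape
    if n < 2:
        raise ValueError("FPCA requires at least two curves")
    if J is not None and J > min(n, M):
        raise ValueError(f"J={J} exceeds min(n, M)={min(n, M)}")

    mu = W.mean(axis=0) if center else np.zeros(M)
    Wc = W - mu
    C_raw = (Wc.T @ Wc) / max(n - 1, 1)
    raw_diag = np.diag(C_raw).copy()

    if smooth:
        C = _local_linear_surface(grid, C_raw, bandwidth)
        sigma2 = float(np.mean(raw_diag - np.diag(C)))
        sigma2 = max(sigma2, 0.0)
    else:
        C = C_raw
        sigma2 = 0.0

    # eigendecomposition in the quadrature metric
    sw = np.sqrt(w)
    A = sw[:, None] * C * sw[None, :]
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] < -1e-8 * max(evals[0], 1e-300):
        warnings.warn("smoothed covariance not PSD; truncating negative "
                      "eigenvalues at zero")
    evals = np.maximum(evals, 0.0)

    total = evals.sum()
    if J is None:
        if total <= 0:
            J = 1
        else:
            J = int(np.searchsorted(np.cumsum(evals) / total, pve) + 1)
            J = min(J, min(n, M))
    lam = evals[:J]
    Phi = evecs[:, :J] / sw[:, None]
    # sign convention: non-negative grid sum, first element positive on ties
    for j in range(J):
        ssum = Phi[:, j].sum()
        if ssum < 0 or (ssum == 0 and Phi[0, j] < 0):
            Phi[:, j] = -Phi[:, j]

    pve_attained = float(lam.sum() / total) if total > 0 else 1.0
    scores = _ce_scores(Wc, Phi, lam, sigma2, w)
    return FPCAResult(mu=mu, Phi=Phi, lam=lam, sigma2_eps=sigma2,
                      scores=scores, pve=pve_attained, grid=grid, lweights=w)


def predict_scores(fp: FPCAResult, Wnew) -> np.ndarray:
    """Conditional-expectation scores for new curves on the same grid."""
    Wnew = np.atleast_2d(np.asarray(Wnew, dtype=float))
    if Wnew.shape[1] != fp.mu.size:
        raise ValueError("new curves are not on the FPCA grid")
    return _ce_scores(Wnew - fp.mu, fp.Phi, fp.lam, fp.sigma2_eps,
                      fp.lweights)


def _ce_scores(Wc, Phi, lam, sigma2, w):
    """``xi_hat = Lam Phi^T diag(w) (Phi Lam Phi^T diag(w) + sigma2 I)^{-1}
    (W - mu)`` per curve; reduces to the weighted projection when the noise
    variance vanishes."""
    if sigma2 < 1e-12:
        return (Wc * w[None, :]) @ Phi
    M = Phi.shape[0]
    B = (lam[:, None] * Phi.T) * w[None, :]           # J x M
    G = Phi @ (lam[:, None] * Phi.T) * w[None, :] + sigma2 * np.eye(M)
    T = np.linalg.solve(G.T, B.T)                      # M x J
    return Wc @ T


def _local_linear_surface(grid, C, h) -> np.ndarray:
    """Local linear smooth of the covariance with the diagonal excluded,
    evaluated on the full grid (including the diagonal).

    The Gaussian product kernel is separable, so every moment over the
    off-diagonal pairs (a, b) factors into one-dimensional sums minus a
    diagonal correction; the whole surface reduces to a handful of M x M
    matrix products followed by a batched 3 x 3 solve.
    """
    M = grid.size
    D = (grid[:, None] - grid[None, :]) / h      # D[a, s]
    K0 = np.exp(-0.5 * D ** 2)
    off = grid[:, None] - grid[None, :]          # off[a, s] = t_a - t_s
    K1 = K0 * off
    K2 = K0 * off ** 2
    cdiag = np.diag(C)

    def cross(Ka, Kb):
        # sum_{a != b} Ka[a, s] Kb[b, t]  for all (s, t)
        return np.outer(Ka.sum(axis=0), Kb.sum(axis=0)) - Ka.T @ Kb

    def crossC(Ka, Kb):
        # sum_{a != b} Ka[a, s] Kb[b, t] C[a, b]
        return Ka.T @ C @ Kb - (Ka * cdiag[:, None]).T @ Kb

    S00 = cross(K0, K0)
    S10, S01 = cross(K1, K0), cross(K0, K1)
    S20, S02, S11 = cross(K2, K0), cross(K0, K2), cross(K1, K1)
    R0, R1, R2 = crossC(K0, K0), crossC(K1, K0), crossC(K0, K1)

    A = np.empty((M, M, 3, 3))
    A[..., 0, 0], A[..., 0, 1], A[..., 0, 2] = S00, S10, S01
    A[..., 1, 0], A[..., 1, 1], A[..., 1, 2] = S10, S20, S11
    A[..., 2, 0], A[..., 2, 1], A[..., 2, 2] = S01, S11, S02
    rhs = np.stack([R0, R1, R2], axis=-1)
    # ridge keeps far-corner systems solvable without affecting the fit
    A += 1e-12 * np.eye(3)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    out = beta[..., 0]
    return 0.5 * (out + out.T)
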