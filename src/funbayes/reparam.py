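"""Spectral reparametrization of penalized spline coefficients.

With penalty matrix ``S = U V U^T`` (eigenvalues sorted descending) and
``b~ = Vt^{1/2} U^T b`` where ``Vt`` carries the K0 positive eigenvalues
followed by positive scaling constants on the (K - K0)-dimensional null
space, the smoothness penalty becomes ``b^T S b = b~_r^T b~_r``: an i.i.d.
normal prior on the first K0 transformed coordinates and a flat prior on the
rest. The design matrix transforms as ``X~ = Vt^{-1/2} U^T X`` so that
``X~^T b~ = X^T b`` and fitted values are invariant.

The null-space scaling constants do not affect the posterior (the prior is
flat in those directions); they are set from the Frobenius norm of the
design so the unpenalized columns are on a scale comparable to the penalized
ones, which helps sampler conditioning. They are recorded for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReparamDesign", "spectral_reparam", "back_transform",
           "forward_transform"]


@dataclass
class ReparamDesign:
    """Eigenstructure of the penalty plus transformed design blocks.

    ``U`` is the K x K orthonormal eigenvector matrix of S, ``d`` the
    diagonal of ``Vt`` (positive eigenvalues, then null-space constants),
    ``Xr``/``Xf`` the n x K0 penalized and n x (K - K0) unpenalized design
    blocks (rows index observations).
    """

    U: np.ndarray
    d: np.ndarray
    Xr: np.ndarray
    Xf: np.ndarray
    K0: int

    @property
    def K(self) -> int:
        return self.d.size

    @property
    def back_map(self) -> np.ndarray:
        """K x K matrix ``U Vt^{-1/2}`` mapping b~ to b."""
        return self.U / np.sqrt(self.d)


def spectral_reparam(X, S, rank_tol: float = 1e-8) -> ReparamDesign:
    """Diagonalize the penalty and transform the design accordingly.

    Parameters
    ----------
    X : (K, n) ndarray or DesignMatrix
        Design with one row per basis function (columns are observations,
        or eigenfunctions for the joint model).
    S : (K, K) ndarray
        Symmetric positive semi-definite penalty.
    rank_tol : float
        Relative eigenvalue threshold defining the penalty rank K0.
    """
    X = getattr(X, "X", X)
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if X.shape[0] != S.shape[0]:
        raise ValueError("X must have K rows matching the penalty dimension")
    if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
        raise ValueError("penalty matrix must be symmetric")

    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    vmax = evals.max()
    if vmax <= 0:
        raise ValueError("degenerate penalty: no positive eigenvalues")
    if evals.min() < -rank_tol * vmax:
        raise ValueError("penalty has a negative eigenvalue beyond tolerance")
    K0 = int(np.sum(evals > rank_tol * vmax))
    if K0 == 0:
        raise ValueError("degenerate penalty: rank zero")
    K = evals.size

    # deterministic sign convention: first entry of largest magnitude made
    # positive (ties broken by index)
    for j in range(K):
        col = evecs[:, j]
        lead = np.argmax(np.abs(col) > 1e-12 * np.abs(col).max())
        if col[lead] < 0:
            evecs[:, j] = -col

    d = np.empty(K)
    d[:K0] = evals[:K0]
    # null-space scaling: squared Frobenius norm of X per column, a single
    # positive constant; the flat prior makes the posterior invariant to it
    d[K0:] = max(np.sum(X ** 2) / X.shape[1], 1e-12)

    Xt = (evecs.T @ X) / np.sqrt(d)[:, None]
    return ReparamDesign(U=evecs, d=d, Xr=Xt[:K0].T, Xf=Xt[K0:].T, K0=K0)


def back_transform(b_tilde, rd: ReparamDesign) -> np.ndarray:
    """Map transformed coefficients back to the original spline basis.

    ``b = U Vt^{-1/2} b~``; accepts a vector or a (draws, K) matrix.
    """
    b_tilde = np.asarray(b_tilde, dtype=float)
    if b_tilde.shape[-1] != rd.K:
        raise ValueError("coefficient length does not match the basis size")
    return b_tilde @ rd.back_map.T


def forward_transform(b, rd: ReparamDesign) -> np.ndarray:
    """Map original-basis coefficients to the transformed scale,
    ``b~ = Vt^{1/2} U^T b``."""
    b = np.asarray(b, dtype=float)
    return (b @ rd.U) * np.sqrt(rd.d)
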