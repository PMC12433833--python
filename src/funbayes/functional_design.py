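"""Functional datasets and quadrature design matrices.

Scalar-on-function regression integrates each observed curve against the
spline basis, ``X_ik = ∫ W_i(t) psi_k(t) dt``, approximated by a Riemann sum
on the common observation grid. The joint FPCA model instead integrates
eigenfunctions against the basis, ``X_jk = ∫ phi_j(t) psi_k(t) dt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .bases import PenalizedBasis

__all__ = ["FunctionalDataset", "DesignMatrix", "riemann_design",
           "eigen_product_design", "quadrature_weights"]


def quadrature_weights(grid) -> np.ndarray:
    """Riemann weights ``L_m = t_{m+1} - t_m`` with the last weight replicated.

    On an equispaced grid of M points these all equal the spacing, matching
    the ``(1/M) * sum`` convention of the simulation designs.
    """
    grid = np.asarray(grid, dtype=float)
    w = np.diff(grid)
    if w.size == 0:
        return np.ones(1)
    return np.append(w, w[-1])


@dataclass
class FunctionalDataset:
    """Dense functional covariates on a shared grid plus outcome data.

    Attributes
    ----------
    W : (n, M) ndarray
        Functional observations, one curve per row.
    grid : (M,) ndarray
        Common observation grid (sorted, within [0, 1] after rescaling).
    lweights : (M,) ndarray
        Quadrature weights L_m.
    Z : (n, p) ndarray or None
        Scalar covariates.
    y : ndarray or None
        Outcome: real vector (Gaussian), 0/1 vector (Bernoulli), or event
        times when paired with ``censor``.
    censor : ndarray or None
        Right-censoring indicator; 0 marks an observed event, 1 a censored
        one (see the survival model docs for this convention).
    extra : dict
        Generator-side ground truth (true linear predictors, scores, ...)
        carried along for evaluation; never used by the models.
    """

    W: np.ndarray
    grid: np.ndarray
    lweights: Optional[np.ndarray] = None
    Z: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    censor: Optional[np.ndarray] = None
    extra: dict = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.W.ndim != 2 or self.W.shape[1] != self.grid.size:
            raise ValueError("W must be n x M with M = len(grid)")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.lweights is None:
            self.lweights = quadrature_weights(self.grid)
        self.lweights = np.asarray(self.lweights, dtype=float)
        if np.any(self.lweights <= 0):
            raise ValueError("quadrature weights must be positive")
        if self.extra is None:
            self.extra = {}

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]

    # matrix views used by the model-assembly layer ------------------------
    @property
    def tmat(self) -> np.ndarray:
        """n x M matrix of observation times (identical rows)."""
        return np.tile(self.grid, (self.n, 1))

    @property
    def lmat(self) -> np.ndarray:
        """n x M matrix of quadrature weights (identical rows)."""
        return np.tile(self.lweights, (self.n, 1))


@dataclass
class DesignMatrix:
    """Finite design produced by numerical integration.

    For ``source == 'riemann'``, ``X`` is K x n with
    ``X[k, i] = sum_m L_m W_i(t_m) psi_k(t_m)``; for
    ``source == 'eigen_product'``, ``X`` is K x J with
    ``X[k, j] = sum_m L_m phi_j(t_m) psi_k(t_m)``.
    """

    X: np.ndarray
    source: str


def riemann_design(data: FunctionalDataset,
                   basis: PenalizedBasis) -> DesignMatrix:
    """Integrate observed curves against the spline basis.

    Raises on any missing value: subjects with incomplete curves must go
    through the FPCA (joint-model) route instead.
    """
    if basis.grid.size != data.grid.size or not np.allclose(basis.grid, data.grid):
        raise ValueError("basis grid does not match data grid")
    if np.any(~np.isfinite(data.W)):
        raise ValueError("W contains missing or non-finite values; "
                         "route incomplete curves through the FPCA path")
    X = basis.Psi.T @ (data.lweights[:, None] * data.W.T)
    return DesignMatrix(X=X, source="riemann")


def eigen_product_design(eigenfunctions, basis: PenalizedBasis,
                         weights=None) -> DesignMatrix:
    """Inner products of eigenfunctions with the spline basis.

    ``eigenfunctions`` is M x J, evaluated on the basis grid. Returns the
    K x J matrix with entries ``sum_m L_m phi_j(t_m) psi_k(t_m)``.
    """
    Phi = np.asarray(eigenfunctions, dtype=float)
    if Phi.ndim != 2 or Phi.shape[0] != basis.grid.size:
        raise ValueError("eigenfunctions must be M x J on the basis grid")
    w = quadrature_weights(basis.grid) if weights is None else np.asarray(weights)
    X = basis.Psi.T @ (w[:, None] * Phi)
    return DesignMatrix(X=X, source="eigen_product")
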