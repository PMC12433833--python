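"""Spline bases for functional coefficients and baseline hazards.

Two constructions live here:

* :func:`build_penalized_basis` — a spline basis ``psi_1(t), ..., psi_K(t)``
  on [0, 1] together with the curvature (Wahba–O'Sullivan) penalty matrix
  ``S = ∫ psi''(t) psi''(t)^T dt``, used to represent functional regression
  coefficients ``beta(t) = sum_k b_k psi_k(t)`` with a smoothness prior/penalty
  ``b^T S b``.
* :func:`build_hazard_basis` — M-spline basis functions (non-negative,
  integrating to one over their support) and their running integrals
  (I-splines, monotone non-decreasing, reaching one at the upper boundary),
  used to model a baseline hazard ``h0(t) = sum_l c_l M_l(t)`` and its
  cumulative version ``H0(t) = sum_l c_l I_l(t)``.

The penalty matrix is computed by numerical quadrature of analytic second
derivatives on a fine grid, which keeps the construction agnostic to the
basis family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import BSpline, CubicSpline

__all__ = [
    "PenalizedBasis",
    "HazardBasis",
    "build_penalized_basis",
    "build_hazard_basis",
]

#: eigenvalues above RANK_TOL * max(eigenvalue) count toward the penalty rank
RANK_TOL = 1e-8

#: number of quadrature points used when integrating products of second
#: derivatives for the penalty matrix
PENALTY_QUAD_POINTS = 2001

_BASIS_KINDS = ("cubic_regression", "cyclic_cubic", "bspline")


@dataclass
class PenalizedBasis:
    """Spline basis evaluated on a grid, with its curvature penalty.

    Attributes
    ----------
    grid : (M,) ndarray
        Ordered observation grid in [0, 1].
    Psi : (M, K) ndarray
        Basis evaluations ``Psi[m, k] = psi_k(grid[m])``.
    S : (K, K) ndarray
        Symmetric positive semi-definite penalty matrix.
    K0 : int
        Rank of ``S``; curvature penalties on cubic bases have a null space
        of dimension 2 (linear functions), cyclic bases of dimension 1
        (constants).
    basis_kind : str
        One of ``cubic_regression``, ``cyclic_cubic``, ``bspline``.
    knots : ndarray
        Knot locations used to build the basis.
    """

    grid: np.ndarray
    Psi: np.ndarray
    S: np.ndarray
    K0: int
    basis_kind: str
    knots: np.ndarray
    _splines: list = field(default_factory=list, repr=False)

    @property
    def K(self) -> int:
        return self.Psi.shape[1]

    def evaluate(self, t) -> np.ndarray:
        """Evaluate all basis functions at arbitrary points ``t`` in [0, 1]."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.column_stack([s(t) for s in self._splines])
        return out

    def to_csv_bundle(self, directory) -> None:
        """Export grid, basis evaluations, and penalty as CSV files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "grid.csv", self.grid, delimiter=",")
        np.savetxt(directory / "psi.csv", self.Psi, delimiter=",")
        np.savetxt(directory / "penalty.csv", self.S, delimiter=",")


@dataclass
class HazardBasis:
    """M-spline / I-spline basis evaluated at observed times.

    ``Mb[i, l] = M_l(times[i])`` and ``Ib[i, l] = I_l(times[i])`` where
    ``I_l(t) = ∫_0^t M_l(u) du``. Every M-spline integrates to one over its
    support, hence every I-spline increases from 0 to 1.
    """

    times: np.ndarray
    Mb: np.ndarray
    Ib: np.ndarray
    df: int
    boundary: tuple
    degree: int
    knots: np.ndarray = None
    _scales: np.ndarray = field(default=None, repr=False)

    @property
    def L(self) -> int:
        return self.df

    def mspline(self, t) -> np.ndarray:
        """Evaluate the M-spline basis at arbitrary times in [0, upper]."""
        return _mspline_eval(np.asarray(t, dtype=float), self.knots,
                             self.degree, self._scales, integral=False)

    def ispline(self, t) -> np.ndarray:
        """Evaluate the I-spline (integrated) basis at times in [0, upper]."""
        return _mspline_eval(np.asarray(t, dtype=float), self.knots,
                             self.degree, self._scales, integral=True)


def build_penalized_basis(grid, K: int = 10, kind: str = "cubic_regression",
                          center: bool = False) -> PenalizedBasis:
    """Construct a spline basis on ``grid`` with its curvature penalty.

    Parameters
    ----------
    grid : array-like
        Sorted observation points in [0, 1], at least ``K`` distinct values.
    K : int
        Number of basis functions (>= 4). Knots are placed at quantiles of
        the grid.
    kind : str
        ``cubic_regression`` — cardinal natural cubic splines (one basis
        function per knot, interpolating an indicator at that knot);
        ``cyclic_cubic`` — periodic cardinal cubic splines, psi_k(0) ==
        psi_k(1); ``bspline`` — ordinary cubic B-splines.
    center : bool
        If True, absorb a weighted sum-to-zero (identifiability) constraint
        into the basis, reducing it to K-1 functions. Off by default: with a
        single functional term the model is identifiable without it.

    Returns
    -------
    PenalizedBasis
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1:
        raise ValueError("grid must be one-dimensional")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted in increasing order")
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid must lie within [0, 1]")
    if K < 4:
        raise ValueError("K must be at least 4")
    if kind not in _BASIS_KINDS:
        raise ValueError(f"unknown basis kind {kind!r}; choose from {_BASIS_KINDS}")
    n_distinct = np.unique(grid).size
    if K > n_distinct:
        raise ValueError(
            f"K={K} exceeds the number of distinct grid points ({n_distinct})")

    if kind == "cubic_regression":
        knots = _quantile_knots(grid, K)
        splines = [CubicSpline(knots, _indicator(K, k), bc_type="natural")
                   for k in range(K)]
    elif kind == "cyclic_cubic":
        # K + 1 knots with the last identified with the first (period 1);
        # basis k interpolates the indicator at knot k, periodically wrapped.
        base = _quantile_knots(grid, K + 1)
        base[0], base[-1] = 0.0, 1.0
        splines = []
        for k in range(K):
            y = np.zeros(K + 1)
            y[k] = 1.0
            if k == 0:
                y[-1] = 1.0
            splines.append(CubicSpline(base, y, bc_type="periodic"))
        knots = base
    else:  # bspline
        n_interior = K - 4
        if n_interior > 0:
            interior = np.quantile(grid, np.linspace(0, 1, n_interior + 2)[1:-1])
        else:
            interior = np.array([])
        t = np.concatenate([np.zeros(4), interior, np.ones(4)])
        splines = [BSpline(t, _indicator(K, k), 3, extrapolate=False)
                   for k in range(K)]
        knots = t

    Psi = np.column_stack([np.nan_to_num(s(grid)) for s in splines])
    if not np.all(np.isfinite(Psi)):
        raise ValueError("basis evaluations are not finite")

    S = _curvature_penalty(splines)
    if center:
        Psi, S, splines = _absorb_constraint(grid, Psi, S, splines)

    evals = np.linalg.eigvalsh(S)
    K0 = int(np.sum(evals > RANK_TOL * evals.max()))
    return PenalizedBasis(grid=grid, Psi=Psi, S=S, K0=K0, basis_kind=kind,
                          knots=knots, _splines=splines)


def _indicator(K, k):
    e = np.zeros(K)
    e[k] = 1.0
    return e


def _quantile_knots(grid, K):
    knots = np.quantile(grid, np.linspace(0, 1, K))
    if np.unique(knots).size != K:
        raise ValueError("quantile knots are not distinct; grid too coarse for K")
    return knots


def _curvature_penalty(splines) -> np.ndarray:
    """``S_kl = ∫_0^1 psi_k''(t) psi_l''(t) dt`` by trapezoid quadrature.

    Second derivatives are evaluated analytically from the piecewise
    polynomial representation; only the integral is numerical.
    """
    tq = np.linspace(0.0, 1.0, PENALTY_QUAD_POINTS)
    D2 = np.column_stack([np.nan_to_num(s.derivative(2)(tq)) for s in splines])
    # composite Simpson weights: products of piecewise-linear second
    # derivatives are piecewise quadratic, so Simpson is essentially exact
    h = tq[1] - tq[0]
    w = np.full(tq.size, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    w *= h / 3.0
    S = (D2 * w[:, None]).T @ D2
    return 0.5 * (S + S.T)


def _absorb_constraint(grid, Psi, S, splines):
    """Project onto the subspace where the weighted column sum vanishes."""
    w = np.diff(grid)
    w = np.append(w, w[-1]) if w.size else np.ones(1)
    cvec = w @ Psi  # 1 x K constraint
    # orthonormal basis of the null space of cvec
    q, _ = np.linalg.qr(np.column_stack([cvec, np.eye(cvec.size)]))
    Q = q[:, 1:]
    Psi_c = Psi @ Q
    S_c = Q.T @ S @ Q

    class _Proj:
        def __init__(self, col):
            self.col = col

        def __call__(self, t):
            vals = np.column_stack([np.nan_to_num(s(t)) for s in splines])
            return vals @ self.col

        def derivative(self, n):
            cols = self.col

            def d(t):
                vals = np.column_stack(
                    [np.nan_to_num(s.derivative(n)(t)) for s in splines])
                return vals @ cols
            return d

    proj = [_Proj(Q[:, j]) for j in range(Q.shape[1])]
    return Psi_c, 0.5 * (S_c + S_c.T), proj


# ---------------------------------------------------------------------------
# M-splines / I-splines for the baseline hazard
# ---------------------------------------------------------------------------

def build_hazard_basis(times, df: int = 5, boundary=None,
                       degree: int = 3) -> HazardBasis:
    """M-spline and I-spline bases evaluated at follow-up times.

    Parameters
    ----------
    times : array-like
        Positive observed times (events or censoring).
    df : int
        Number of basis functions L (default 5). Must satisfy
        ``df >= degree + 1``; interior knots (``df - degree - 1`` of them)
        are placed at quantiles of ``times``.
    boundary : (float, float), optional
        Support of the basis. Defaults to ``(0.99 * min(times),
        1.01 * max(times))`` so that every observed time is interior.
    degree : int
        Polynomial degree of the M-splines (default 3).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if boundary is None:
        boundary = (0.99 * times.min(), 1.01 * times.max())
    lower, upper = float(boundary[0]), float(boundary[1])
    if not (lower < times.min() and upper > times.max()):
        raise ValueError("boundary must strictly bracket the observed times")
    if df < degree + 1:
        raise ValueError("df must be at least degree + 1")

    n_interior = df - degree - 1
    if n_interior > 0:
        interior = np.quantile(times, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    knots = np.concatenate([np.full(degree + 1, lower), interior,
                            np.full(degree + 1, upper)])
    # M_l = (degree + 1) / (knots[l + degree + 1] - knots[l]) * B_l, which
    # normalizes each B-spline to integrate to one over its support.
    k = degree + 1
    spans = knots[k:k + df] - knots[:df]
    scales = k / spans

    Mb = _mspline_eval(times, knots, degree, scales, integral=False)
    Ib = _mspline_eval(times, knots, degree, scales, integral=True)
    return HazardBasis(times=times, Mb=Mb, Ib=Ib, df=df,
                       boundary=(lower, upper), degree=degree, knots=knots,
                       _scales=scales)


def _mspline_eval(t, knots, degree, scales, integral: bool) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lower, upper = knots[0], knots[-1]
    if np.any(t < 0) or np.any(t > upper * (1 + 1e-12)):
        raise ValueError("evaluation time outside [0, upper boundary]")
    L = scales.size
    out = np.zeros((t.size, L))
    inside = (t >= lower) & (t <= upper)
    above = t > upper  # numerically equal to upper after clipping guard
    tc = np.clip(t, lower, upper)
    for l in range(L):
        c = np.zeros(L)
        c[l] = 1.0
        b = BSpline(knots, c, degree, extrapolate=False)
        if integral:
            ib = b.antiderivative()
            vals = scales[l] * (np.nan_to_num(ib(tc)) - ib(lower))
            out[inside, l] = vals[inside]
            out[t >= upper, l] = scales[l] * (ib(upper - 1e-12) - ib(lower))
            # times below the lower boundary have zero accumulated mass
            out[t < lower, l] = 0.0
        else:
            vals = scales[l] * np.nan_to_num(b(tc))
            out[inside, l] = vals[inside]
    if integral:
        out = np.clip(out, 0.0, 1.0)
    del above
    return out
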