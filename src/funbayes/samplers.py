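"""No-U-Turn sampler and parameter transforms.

The models in this package expose differentiable log posterior densities on
an unconstrained parameter vector; this module provides the Hamiltonian
Monte Carlo machinery that draws from them. The implementation follows the
classic recursive tree-doubling construction with a slice variable, dual
averaging of the step size toward a target acceptance statistic during
warmup, and a diagonal mass matrix estimated from an intermediate warmup
window.

Also here: the stick-breaking transform between the (L-1)-dimensional
unconstrained space and the L-simplex (used for M-spline hazard weights),
with its log-Jacobian and a hand-coded reverse-mode gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["nuts_sample", "NUTSResult", "simplex_constrain",
           "simplex_constrain_grad", "simplex_unconstrain"]

_MAX_DELTA = 1000.0  # energy error declaring a divergent transition


@dataclass
class NUTSResult:
    draws: np.ndarray            # (n_draws, dim)
    logp: np.ndarray             # (n_draws,)
    divergences: int = 0
    step_size: float = 0.0
    mass_diag: np.ndarray = None
    mean_accept: float = 0.0
    treedepths: np.ndarray = None


def _leapfrog(logp_grad, x, p, g, eps, inv_mass):
    p = p + 0.5 * eps * g
    x = x + eps * (inv_mass * p)
    lp, g = logp_grad(x)
    p = p + 0.5 * eps * g
    return x, p, g, lp


def _find_initial_step(logp_grad, x0, lp0, g0, inv_mass, rng):
    eps = 1.0
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    joint0 = lp0 - 0.5 * np.sum(inv_mass * p0 ** 2)
    _, p1, _, lp1 = _leapfrog(logp_grad, x0, p0, g0, eps, inv_mass)
    joint1 = lp1 - 0.5 * np.sum(inv_mass * p1 ** 2)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, _, lp1 = _leapfrog(logp_grad, x0, p0, g0, eps, inv_mass)
        joint1 = lp1 - 0.5 * np.sum(inv_mass * p1 ** 2)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * math.log(0.5):
            break
    return eps


def _build_tree(logp_grad, x, p, g, logu, direction, depth, eps, inv_mass,
                joint0):
    """Recursive doubling; returns the tuple
    (x-, p-, g-, x+, p+, g+, x_prop, lp_prop, g_prop, n, stop, alpha,
    n_alpha, divergent)."""
    if depth == 0:
        de = direction * eps
        p1 = p + 0.5 * de * g
        x1 = x + de * (inv_mass * p1)
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * de * g1
        joint = lp1 - 0.5 * (p1 @ (inv_mass * p1))
        if joint != joint:  # NaN guard
            joint = -np.inf
        div = (logu - _MAX_DELTA) > joint
        alpha = math.exp(min(0.0, joint - joint0)) if joint > -np.inf else 0.0
        return (x1, p1, g1, x1, p1, g1, x1, lp1, g1,
                int(logu <= joint), div, alpha, 1, div)

    t1 = _build_tree(logp_grad, x, p, g, logu, direction, depth - 1, eps,
                     inv_mass, joint0)
    if t1[10]:
        return t1
    (xm, pm, gm, xp, pp, gp, xc, lpc, gc, n1, _, a1, na1, div1) = t1
    if direction == -1:
        t2 = _build_tree(logp_grad, xm, pm, gm, logu, direction, depth - 1,
                         eps, inv_mass, joint0)
        xm, pm, gm = t2[0], t2[1], t2[2]
    else:
        t2 = _build_tree(logp_grad, xp, pp, gp, logu, direction, depth - 1,
                         eps, inv_mass, joint0)
        xp, pp, gp = t2[3], t2[4], t2[5]
    n2, stop2, a2, na2, div2 = t2[9], t2[10], t2[11], t2[12], t2[13]
    total = n1 + n2
    if n2 > 0 and _tree_rng.uniform() < n2 / total:
        xc, lpc, gc = t2[6], t2[7], t2[8]
    dx = xp - xm
    uturn = (dx @ (inv_mass * pm)) < 0 or (dx @ (inv_mass * pp)) < 0
    return (xm, pm, gm, xp, pp, gp, xc, lpc, gc, total,
            stop2 or uturn, a1 + a2, na1 + na2, div1 or div2)


_tree_rng = None  # module-level RNG bound during a sampling run


def nuts_sample(logp_grad, x0, n_warmup=500, n_draws=500, seed=0,
                target_accept=0.8, max_treedepth=10) -> NUTSResult:
    """Draw from a log density with gradient using the No-U-Turn sampler.

    Parameters
    ----------
    logp_grad : callable
        Maps an unconstrained vector to ``(log_density, gradient)``.
    x0 : array-like
        Initial unconstrained position.
    n_warmup, n_draws : int
        Adaptation and retained iterations.
    seed : int
        Seed for the run's random stream.
    target_accept : float
        Dual-averaging target for the mean acceptance statistic.
    """
    global _tree_rng
    rng = np.random.default_rng(seed)
    _tree_rng = rng
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    lp, g = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial log posterior is not finite")

    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, x, lp, g, inv_mass, rng)

    # dual averaging state
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # mass-matrix estimation window (fractions of warmup)
    w_start, w_end = int(0.25 * n_warmup), int(0.85 * n_warmup)
    acc = np.zeros(dim)
    acc2 = np.zeros(dim)
    n_acc = 0

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=np.int8)
    divergences = 0
    accept_sum, accept_n = 0.0, 0

    total = n_warmup + n_draws
    for it in range(total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = lp - 0.5 * np.sum(inv_mass * p0 ** 2)
        logu = joint0 + math.log(rng.uniform())
        x_minus = x_plus = x
        p_minus = p_plus = p0
        g_minus = g_plus = g
        x_prop, lp_prop, g_prop = x, lp, g
        n_valid, depth, stop = 1, 0, False
        alpha_sum, n_alpha = 0.0, 0
        diverged = False
        while not stop and depth < max_treedepth:
            direction = -1 if rng.uniform() < 0.5 else 1
            if direction == -1:
                t = _build_tree(logp_grad, x_minus, p_minus, g_minus, logu,
                                direction, depth, eps, inv_mass, joint0)
                x_minus, p_minus, g_minus = t[0], t[1], t[2]
            else:
                t = _build_tree(logp_grad, x_plus, p_plus, g_plus, logu,
                                direction, depth, eps, inv_mass, joint0)
                x_plus, p_plus, g_plus = t[3], t[4], t[5]
            t_n, t_stop, t_alpha, t_nalpha, t_div = t[9], t[10], t[11], \
                t[12], t[13]
            if not t_stop and t_n > 0:
                if rng.uniform() < min(1.0, t_n / n_valid):
                    x_prop, lp_prop, g_prop = t[6], t[7], t[8]
            n_valid += t_n
            alpha_sum += t_alpha
            n_alpha += t_nalpha
            diverged = diverged or t_div
            dx = x_plus - x_minus
            stop = t_stop or (dx @ (inv_mass * p_minus)) < 0 or \
                (dx @ (inv_mass * p_plus)) < 0
            depth += 1

        x, lp, g = x_prop, lp_prop, g_prop
        accept_stat = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if w_start <= it < w_end:
                acc += x
                acc2 += x * x
                n_acc += 1
            if it == w_end - 1 and n_acc > 10:
                var = acc2 / n_acc - (acc / n_acc) ** 2
                var = np.maximum(var, 1e-10)
                # regularize toward unit scale (small-sample shrinkage)
                var = (n_acc / (n_acc + 5.0)) * var + (5.0 / (n_acc + 5.0))
                inv_mass = var
                eps = _find_initial_step(logp_grad, x, lp, g, inv_mass, rng)
                mu = math.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar) if adapt_count > 0 else eps
        else:
            j = it - n_warmup
            draws[j] = x
            logps[j] = lp
            depths[j] = depth
            if diverged:
                divergences += 1
            accept_sum += accept_stat
            accept_n += 1

    _tree_rng = None
    return NUTSResult(draws=draws, logp=logps, divergences=divergences,
                      step_size=eps, mass_diag=1.0 / inv_mass,
                      mean_accept=accept_sum / max(accept_n, 1),
                      treedepths=depths)


# ---------------------------------------------------------------------------
# simplex (stick-breaking) transform
# ---------------------------------------------------------------------------

def _sigmoid(v):
    return np.where(v >= 0, 1.0 / (1.0 + np.exp(-v)),
                    np.exp(v) / (1.0 + np.exp(v)))


def simplex_constrain(y):
    """Map an unconstrained (L-1)-vector to the open L-simplex.

    Returns ``(x, log_det_jacobian, cache)`` where the cache is consumed by
    :func:`simplex_constrain_grad`. The construction breaks the remaining
    stick by a logistic fraction at each step, with an offset making
    ``y = 0`` map to the uniform vector.
    """
    y = np.asarray(y, dtype=float)
    Lm1 = y.size
    L = Lm1 + 1
    x = np.empty(L)
    z = np.empty(Lm1)
    sticks = np.empty(Lm1)
    stick = 1.0
    logdet = 0.0
    for k in range(Lm1):
        zk = float(_sigmoid(y[k] - math.log(L - 1 - k)))
        zk = min(max(zk, 1e-15), 1 - 1e-15)
        sticks[k] = stick
        z[k] = zk
        x[k] = stick * zk
        logdet += math.log(zk) + math.log1p(-zk) + math.log(stick)
        stick *= (1.0 - zk)
    x[Lm1] = stick
    return x, logdet, (z, sticks)


def simplex_constrain_grad(g_x, cache):
    """Backpropagate a gradient w.r.t. the simplex vector (plus the
    log-Jacobian term) to the unconstrained coordinates."""
    z, sticks = cache
    Lm1 = z.size
    g_y = np.empty(Lm1)
    a_stick = g_x[Lm1]  # x_L = remaining stick
    for k in range(Lm1 - 1, -1, -1):
        zk, st = z[k], sticks[k]
        a_z = g_x[k] * st - a_stick * st
        a_z += 1.0 / zk - 1.0 / (1.0 - zk)          # log-Jacobian terms
        a_st_local = g_x[k] * zk + a_stick * (1.0 - zk) + 1.0 / st
        g_y[k] = a_z * zk * (1.0 - zk)
        a_stick = a_st_local
    return g_y


def simplex_unconstrain(x):
    """Inverse of :func:`simplex_constrain` for an interior simplex point."""
    x = np.asarray(x, dtype=float)
    L = x.size
    y = np.empty(L - 1)
    stick = 1.0
    for k in range(L - 1):
        zk = x[k] / stick
        zk = min(max(zk, 1e-12), 1 - 1e-12)
        y[k] = math.log(zk / (1 - zk)) + math.log(L - 1 - k)
        stick *= (1 - zk)
    return y
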