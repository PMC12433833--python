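"""Model log posteriors against independently coded density oracles.

Every oracle here is written directly from the model formulas with
scipy.stats building blocks and naive loops — no shared code with the
implementation paths being checked.
"""

import numpy as np
import pytest
from scipy.stats import norm, invgamma, bernoulli

import funbayes as fb
from funbayes import bayes_models as bm
from funbayes.bases import build_hazard_basis


def _ig_logpdf(v, a, b):
    return invgamma.logpdf(v, a, scale=b)


@pytest.fixture(scope="module")
def sofr_setup():
    basis = fb.build_penalized_basis(fb.default_grid(50), K=10)
    data = fb.simulate_sofr(fb.DGPConfig(n=25, tau=2, seed=8, holdout=5))
    data.Z = np.random.default_rng(5).standard_normal((25, 2))
    X = fb.riemann_design(data, basis).X
    rd = fb.spectral_reparam(X, basis.S)
    return basis, data, X, rd


def _random_sofr_params(rd, rng, gaussian=True):
    p = {"eta0": float(rng.standard_normal()),
         "br": rng.standard_normal(rd.K0),
         "bf": rng.standard_normal(rd.K - rd.K0),
         "gamma": rng.standard_normal(2),
         "sigma_b2": float(np.exp(rng.standard_normal()))}
    if gaussian:
        p["sigma"] = float(np.exp(0.3 * rng.standard_normal()))
    return p


def test_sofr_gaussian_matches_direct_penalty_oracle(sofr_setup, rng):
    """The reparametrized log posterior equals an oracle written from the
    untransformed formulation: eta = eta0 + X^T b + Z gamma with prior
    exp(-b^T S b / 2 sigma_b^2) normalized over the penalized subspace."""
    basis, data, X, rd = sofr_setup
    for _ in range(5):
        p = _random_sofr_params(rd, rng)
        spec = bm.ModelSpec(family="gaussian", Xr=rd.Xr, Xf=rd.Xf,
                            Z=data.Z, y=data.y)
        lp = bm.sofr_log_posterior(spec, p)

        bt = np.concatenate([p["br"], p["bf"]])
        b = fb.back_transform(bt, rd)
        eta = p["eta0"] + X.T @ b + data.Z @ p["gamma"]
        oracle = norm.logpdf(data.y, eta, p["sigma"]).sum()
        oracle += -0.5 * rd.K0 * np.log(2 * np.pi * p["sigma_b2"]) \
            - b @ basis.S @ b / (2 * p["sigma_b2"])
        oracle += _ig_logpdf(p["sigma_b2"], 0.001, 0.001)
        assert abs(lp - oracle) < 1e-6 * max(1, abs(oracle))


def test_sofr_closed_form_special_cases(sofr_setup):
    basis, data, X, rd = sofr_setup
    n = data.n
    p0 = {"eta0": 0.0, "br": np.zeros(rd.K0), "bf": np.zeros(rd.K - rd.K0),
          "gamma": np.zeros(2), "sigma_b2": 1.0, "sigma": 1.0}
    spec = bm.ModelSpec(family="gaussian", Xr=rd.Xr, Xf=rd.Xf, Z=data.Z,
                        y=data.y)
    lp = bm.sofr_log_posterior(spec, p0)
    loglik = -0.5 * n * np.log(2 * np.pi) - 0.5 * np.sum(data.y ** 2)
    prior = -0.5 * rd.K0 * np.log(2 * np.pi) + _ig_logpdf(1.0, 0.001, 0.001)
    assert abs(lp - (loglik + prior)) < 1e-8

    # Bernoulli with eta == 0: log-likelihood is -n log 2
    yb = (data.y > 0).astype(float)
    specb = bm.ModelSpec(family="bernoulli_logit", Xr=rd.Xr, Xf=rd.Xf,
                         Z=data.Z, y=yb)
    pb = {k: v for k, v in p0.items() if k != "sigma"}
    lpb = bm.sofr_log_posterior(specb, pb)
    assert abs(lpb - (-n * np.log(2) + prior)) < 1e-8

    # domain guard
    assert bm.sofr_log_posterior(spec, {**p0, "sigma_b2": -1.0}) == -np.inf


def test_bernoulli_matches_pmf_oracle(sofr_setup, rng):
    basis, data, X, rd = sofr_setup
    yb = (rng.uniform(size=data.n) < 0.4).astype(float)
    spec = bm.ModelSpec(family="bernoulli_logit", Xr=rd.Xr, Xf=rd.Xf,
                        Z=data.Z, y=yb)
    p = _random_sofr_params(rd, rng, gaussian=False)
    lp = bm.sofr_log_posterior(spec, p)
    eta = p["eta0"] + rd.Xr @ p["br"] + rd.Xf @ p["bf"] + data.Z @ p["gamma"]
    prob = 1 / (1 + np.exp(-eta))
    oracle = bernoulli.logpmf(yb, prob).sum()
    oracle += norm.logpdf(p["br"], 0, np.sqrt(p["sigma_b2"])).sum()
    oracle += _ig_logpdf(p["sigma_b2"], 0.001, 0.001)
    assert abs(lp - oracle) < 1e-6 * max(1, abs(oracle))


# ---------------------------------------------------------------------------
# Cox likelihood
# ---------------------------------------------------------------------------

def test_cox_unit_exponential_cases():
    """A single subject under constant unit hazard on [0, 1]: log-lik is -y
    for both an observed event (log h0 + eta - H0) and a censored one."""
    y = np.array([0.37])
    hb = build_hazard_basis(y, df=1, degree=0, boundary=(0.0, 1.0))
    for delta in (0.0, 1.0):
        ll = bm.cox_log_likelihood(y, np.array([delta]), np.zeros(1),
                                   np.array([1.0]), hb)
        assert abs(ll - (-0.37)) < 1e-10


def test_cox_likelihood_vs_quadrature_oracle(rng):
    """Random simplex weights and linear predictors, n = 20: the analytic
    I-spline cumulative hazard matches a 10,001-point trapezoid oracle."""
    times = rng.uniform(0.2, 3.0, 20)
    delta = (rng.uniform(size=20) < 0.4).astype(float)
    hb = build_hazard_basis(times, df=5)
    eta = 0.5 * rng.standard_normal(20)
    c = rng.dirichlet(np.ones(5))

    ll = bm.cox_log_likelihood(times, delta, eta, c, hb)

    # integrate from the lower support boundary (hazard is zero below it)
    tq = np.linspace(hb.boundary[0], hb.boundary[1], 10001)
    h0q = hb.mspline(tq) @ c
    H0q = np.concatenate([[0], np.cumsum(0.5 * (h0q[1:] + h0q[:-1])
                                         * np.diff(tq))])
    h0 = np.interp(times, tq, h0q)
    H0 = np.interp(times, tq, H0q)
    oracle = np.sum((1 - delta) * (np.log(h0) + eta)
                    - H0 * np.exp(eta))
    assert abs(ll - oracle) < 1e-5 * max(1, abs(oracle))


def test_cox_scale_invariance(rng):
    """(c, eta0) -> (a c, eta0 - log a) leaves the likelihood unchanged:
    the non-identifiability that motivates the simplex constraint."""
    times = rng.uniform(0.2, 3.0, 15)
    delta = (rng.uniform(size=15) < 0.5).astype(float)
    hb = build_hazard_basis(times, df=5)
    c = rng.dirichlet(np.ones(5))
    eta = rng.standard_normal(15)
    base = bm.cox_log_likelihood(times, delta, eta, c, hb)
    for a in (0.1, 3.7, 42.0):
        shifted = bm.cox_log_likelihood(times, delta, eta - np.log(a),
                                        a * c, hb)
        assert abs(shifted - base) < 1e-8 * max(1, abs(base))


def test_cox_zero_hazard_at_event_is_impossible():
    y = np.array([0.5, 2.9])
    hb = build_hazard_basis(y, df=5)
    c = np.zeros(5)
    c[-1] = 1.0  # all mass on the last basis: h0(0.5) == 0
    ll = bm.cox_log_likelihood(y, np.zeros(2), np.zeros(2), c, hb)
    assert ll == -np.inf


# ---------------------------------------------------------------------------
# joint and FoSR log posteriors
# ---------------------------------------------------------------------------

def test_joint_log_posterior_matches_naive_oracle(rng):
    n, M, J = 10, 20, 2
    g = fb.default_grid(M)
    basis = fb.build_penalized_basis(g, K=6)
    Phi = fb.default_eigenfunctions(g, J)
    data = fb.simulate_sofr(fb.DGPConfig(n=n, M=M, tau=1, seed=1, noise_sd=2,
                                         eigenvalues=(4.0, 2.0), holdout=2))
    dm = fb.eigen_product_design(Phi, basis, weights=data.lweights)
    rd = fb.spectral_reparam(dm.X, basis.S)
    xi_hat = rng.standard_normal((n, J))
    spec = bm.ModelSpec(family="joint_glm", Xr=rd.Xr, Xf=rd.Xf,
                        y=data.y, W=data.W, Phi=Phi, xi_hat=xi_hat)
    p = {"eta0": 0.3, "br": rng.standard_normal(rd.K0),
         "bf": rng.standard_normal(rd.K - rd.K0),
         "sigma_b2": 0.7, "xi": rng.standard_normal((n, J)),
         "lam": np.array([1.5, 0.6]), "sigma_eps2": 2.2, "sigma": 1.3}
    lp = bm.joint_log_posterior(spec, p)

    # naive double-loop oracle
    v = rd.Xr @ p["br"] + rd.Xf @ p["bf"]
    oracle = 0.0
    for i in range(n):
        eta_i = p["eta0"] + p["xi"][i] @ v
        oracle += norm.logpdf(data.y[i], eta_i, p["sigma"])
        for m in range(M):
            fit = sum(p["xi"][i, j] * Phi[m, j] for j in range(J))
            oracle += norm.logpdf(data.W[i, m], fit, np.sqrt(p["sigma_eps2"]))
        for j in range(J):
            oracle += norm.logpdf(p["xi"][i, j], xi_hat[i, j],
                                  np.sqrt(p["lam"][j]))
    for j in range(J):
        oracle += _ig_logpdf(p["lam"][j], 0.001, 0.001)
    oracle += _ig_logpdf(p["sigma_eps2"], 0.001, 0.001)
    oracle += norm.logpdf(p["br"], 0, np.sqrt(p["sigma_b2"])).sum()
    oracle += _ig_logpdf(p["sigma_b2"], 0.001, 0.001)
    assert abs(lp - oracle) < 1e-6 * max(1, abs(oracle))

    # zero-centered score prior shifts only the score terms
    spec0 = bm.ModelSpec(family="joint_glm", Xr=rd.Xr, Xf=rd.Xf, y=data.y,
                         W=data.W, Phi=Phi, xi_hat=xi_hat,
                         score_prior="zero_centered")
    lp0 = bm.joint_log_posterior(spec0, p)
    shift = sum(norm.logpdf(p["xi"][i, j], 0, np.sqrt(p["lam"][j]))
                - norm.logpdf(p["xi"][i, j], xi_hat[i, j],
                              np.sqrt(p["lam"][j]))
                for i in range(n) for j in range(J))
    assert abs(lp0 - (lp + shift)) < 1e-8 * max(1, abs(lp))


def test_joint_degenerate_measurement_case(rng):
    """W identical to Phi xi^T: the measurement term collapses to the
    zero-residual normal constant."""
    n, M, J = 6, 15, 2
    g = fb.default_grid(M)
    basis = fb.build_penalized_basis(g, K=5)
    Phi = fb.default_eigenfunctions(g, J)
    xi = rng.standard_normal((n, J))
    W = xi @ Phi.T
    dm = fb.eigen_product_design(Phi, basis)
    rd = fb.spectral_reparam(dm.X, basis.S)
    spec = bm.ModelSpec(family="joint_glm", Xr=rd.Xr, Xf=rd.Xf,
                        y=np.zeros(n), W=W, Phi=Phi, xi_hat=xi)
    s_eps = 0.8
    p = {"eta0": 0.0, "br": np.zeros(rd.K0), "bf": np.zeros(rd.K - rd.K0),
         "sigma_b2": 1.0, "xi": xi, "lam": np.ones(J), "sigma_eps2": s_eps,
         "sigma": 1.0}
    lp = bm.joint_log_posterior(spec, p)
    meas = -0.5 * n * M * np.log(2 * np.pi * s_eps)
    rest = (norm.logpdf(np.zeros(n), 0, 1).sum()
            + norm.logpdf(xi, xi, 1).sum()  # score prior at its center
            + 2 * _ig_logpdf(1.0, 0.001, 0.001)
            + _ig_logpdf(s_eps, 0.001, 0.001)
            - 0.5 * rd.K0 * np.log(2 * np.pi)
            + _ig_logpdf(1.0, 0.001, 0.001))
    assert abs(lp - (meas + rest)) < 1e-6


def test_joint_requires_scores():
    with pytest.raises(ValueError):
        bm.joint_log_posterior(
            bm.ModelSpec(family="joint_glm", Xr=np.ones((2, 1))), {})


def test_fosr_log_posterior_matches_naive_oracle(rng):
    n, M, J, P = 8, 20, 2, 2
    g = fb.default_grid(M)
    basis = fb.build_penalized_basis(g, K=6)
    Phi = fb.default_eigenfunctions(g, J)
    Y = rng.standard_normal((n, M))
    Xs = np.column_stack([np.ones(n), rng.standard_normal(n)])
    spec = bm.ModelSpec(family="fosr_gaussian", Y=Y, Xs=Xs, Psi=basis.Psi,
                        S=basis.S, K0=basis.K0, Phi=Phi)
    p = {"b": rng.standard_normal((P, basis.K)),
         "xi": rng.standard_normal((n, J)),
         "lam": np.array([2.0, 0.9]), "sigma_eps2": 1.7,
         "sigma_p2": np.array([0.8, 1.4])}
    lp = bm.fosr_log_posterior(spec, p)

    oracle = 0.0
    for i in range(n):
        for m in range(M):
            mean = sum(Xs[i, q] * (p["b"][q] @ basis.Psi[m])
                       for q in range(P))
            mean += sum(p["xi"][i, j] * Phi[m, j] for j in range(J))
            oracle += norm.logpdf(Y[i, m], mean, np.sqrt(p["sigma_eps2"]))
        for j in range(J):
            oracle += norm.logpdf(p["xi"][i, j], 0, np.sqrt(p["lam"][j]))
    for q in range(P):
        bq = p["b"][q]
        oracle += -0.5 * basis.K0 * np.log(2 * np.pi * p["sigma_p2"][q]) \
            - bq @ basis.S @ bq / (2 * p["sigma_p2"][q])
        oracle += _ig_logpdf(p["sigma_p2"][q], 0.001, 0.001)
    for j in range(J):
        oracle += _ig_logpdf(p["lam"][j], 0.001, 0.001)
    oracle += _ig_logpdf(p["sigma_eps2"], 0.001, 0.001)
    assert abs(lp - oracle) < 1e-6 * max(1, abs(oracle))

    # zero coefficients / zero scores: Gaussian density of Y at 0 plus priors
    p0 = {**p, "b": np.zeros((P, basis.K)), "xi": np.zeros((n, J))}
    lp0 = bm.fosr_log_posterior(spec, p0)
    lik0 = norm.logpdf(Y, 0, np.sqrt(p["sigma_eps2"])).sum()
    assert lp0 < 0 and abs(
        (lp0 - lik0)
        - (norm.logpdf(np.zeros((n, J)), 0, np.sqrt(p["lam"])).sum()
           + sum(-0.5 * basis.K0 * np.log(2 * np.pi * p["sigma_p2"][q])
                 for q in range(P))
           + sum(_ig_logpdf(p["sigma_p2"][q], 0.001, 0.001)
                 for q in range(P))
           + sum(_ig_logpdf(p["lam"][j], 0.001, 0.001) for j in range(J))
           + _ig_logpdf(p["sigma_eps2"], 0.001, 0.001))) < 1e-6


def test_fosr_grid_mismatch_raises(rng):
    g = fb.default_grid(20)
    basis = fb.build_penalized_basis(g, K=5)
    spec = bm.ModelSpec(family="fosr_gaussian", Y=rng.standard_normal((4, 30)),
                        Xs=np.ones((4, 1)), Psi=basis.Psi, S=basis.S,
                        K0=basis.K0, Phi=fb.default_eigenfunctions(g, 2))
    with pytest.raises(ValueError):
        bm.fosr_log_posterior(spec, {})


def test_fosr_intercept_limit_recovers_mean_curve(rng):
    """P=1 intercept-only design with xi = 0 and a diffuse smoothing
    variance: the optimal spline coefficients are the least-squares
    projection of the mean curve onto the basis."""
    n, M = 40, 30
    g = fb.default_grid(M)
    basis = fb.build_penalized_basis(g, K=6)
    truth = np.sin(2 * np.pi * g)
    Y = truth[None, :] + 0.1 * rng.standard_normal((n, M))
    Xs = np.ones((n, 1))
    # closed-form least squares oracle
    b_ls = np.linalg.lstsq(basis.Psi, Y.mean(axis=0), rcond=None)[0]

    # maximizing the likelihood part over b at huge sigma_p2 (prior off)
    spec = bm.ModelSpec(family="fosr_gaussian", Y=Y, Xs=Xs, Psi=basis.Psi,
                        S=basis.S, K0=basis.K0,
                        Phi=fb.default_eigenfunctions(g, 1))
    from scipy.optimize import minimize

    def nll(bvec):
        p = {"b": bvec[None, :], "xi": np.zeros((n, 1)),
             "lam": np.ones(1), "sigma_eps2": 0.01,
             "sigma_p2": np.array([1e12])}
        return -bm.fosr_log_posterior(spec, p)

    res = minimize(nll, np.zeros(basis.K), method="BFGS")
    assert np.abs(basis.Psi @ (res.x - b_ls)).max() < 1e-3
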