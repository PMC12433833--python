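"""Reconstruction, credible bands, scalar tables, and MCMC diagnostics."""

import numpy as np
import pytest

import funbayes as fb
from funbayes.posterior_summary import (cma_band, reconstruct_beta,
                                        scalar_coefficient_table,
                                        diagnostics, plot_bands, trace_data)


@pytest.fixture(scope="module")
def rd_basis():
    basis = fb.build_penalized_basis(fb.default_grid(50), K=8)
    data = fb.simulate_sofr(fb.DGPConfig(n=30, tau=2, seed=2, holdout=5))
    X = fb.riemann_design(data, basis).X
    rd = fb.spectral_reparam(X, basis.S)
    return rd, basis


def test_reconstruct_zero_roundtrip_linearity(rd_basis, rng):
    rd, basis = rd_basis
    K = rd.K
    assert np.allclose(reconstruct_beta(np.zeros((3, K)), rd, basis), 0.0)

    bstar = rng.standard_normal(K)
    bt = fb.forward_transform(bstar, rd)
    row = reconstruct_beta(bt[None, :], rd, basis)[0]
    assert np.abs(row - basis.Psi @ bstar).max() < 1e-10

    draws = rng.standard_normal((100, K))
    curves = reconstruct_beta(draws, rd, basis)
    mean_curve = reconstruct_beta(draws.mean(axis=0)[None, :], rd, basis)[0]
    assert np.abs(curves.mean(axis=0) - mean_curve).max() < 1e-10


def test_cma_band_joint_coverage_by_construction(rng):
    """At least (1 - alpha) of the posterior curves lie entirely inside
    the CMA band, up to the 1/Q resolution of the empirical quantile."""
    Q, M = 500, 40
    draws = rng.standard_normal((Q, M)) @ np.diag(np.linspace(0.5, 2, M))
    s = cma_band(draws, alpha=0.05)
    inside = np.all((draws >= s.cma_lo) & (draws <= s.cma_hi), axis=1)
    assert inside.mean() >= 0.95 - 1.0 / Q


def test_cma_contains_pointwise_everywhere(rng):
    draws = rng.standard_normal((400, 30)) * np.linspace(0.1, 3, 30)
    s = cma_band(draws)
    assert np.all(s.cma_lo <= s.pointwise_lo + 1e-12)
    assert np.all(s.pointwise_hi <= s.cma_hi + 1e-12)
    assert np.all(s.pointwise_lo <= s.beta_hat)
    assert np.all(s.beta_hat <= s.pointwise_hi)


def test_cma_multiplier_is_normal_quantile_at_single_point():
    rng = np.random.default_rng(77)
    draws = rng.standard_normal((10000, 1))
    s = cma_band(draws, alpha=0.05)
    assert abs(s.q_d - 1.96) < 0.1


def test_cma_degenerate_coordinate(rng):
    draws = rng.standard_normal((200, 3))
    draws[:, 1] = 4.2  # constant coordinate: zero posterior sd
    with pytest.warns(UserWarning, match="degenerate"):
        s = cma_band(draws)
    assert np.isclose(s.cma_lo[1], 4.2) and np.isclose(s.cma_hi[1], 4.2)
    assert np.isfinite(s.q_d)


def test_pointwise_quantile_option(rng):
    draws = rng.standard_normal((2000, 5)) + np.arange(5)
    s = cma_band(draws, pointwise="quantile")
    assert np.all(s.pointwise_lo < s.pointwise_hi)
    with pytest.raises(ValueError):
        cma_band(draws, pointwise="nope")


def test_scalar_coefficient_table(rng):
    # degenerate draws
    t = scalar_coefficient_table(np.full((50, 1), 2.5), names=["age"])
    assert t.loc[0, "formatted"] == "2.500 (2.500, 2.500)"
    # normal draws with known moments
    g = rng.normal(0.063, 0.0049, size=(10000, 1))
    t = scalar_coefficient_table(g)
    assert abs(t.loc[0, "estimate"] - 0.063) < 0.001
    assert abs(t.loc[0, "lo"] - (0.063 - 1.96 * 0.0049)) < 0.0005
    assert abs(t.loc[0, "hi"] - (0.063 + 1.96 * 0.0049)) < 0.0005
    # symmetric draws straddle zero
    t0 = scalar_coefficient_table(rng.standard_normal((5000, 1)))
    assert t0.loc[0, "lo"] < 0 < t0.loc[0, "hi"]


def _fake_draws(chains_arrays, divergences=0):
    from funbayes.bayes_models import PosteriorDraws, SamplerConfig
    arr = np.stack(chains_arrays)[:, :, None]
    return PosteriorDraws(params={"theta": arr[..., 0]},
                          divergences=np.array([divergences]
                                               * arr.shape[0]),
                          step_sizes=np.ones(arr.shape[0]),
                          mean_accept=np.ones(arr.shape[0]),
                          config=SamplerConfig(chains=arr.shape[0]))


def test_diagnostics_identical_chains(rng):
    x = rng.standard_normal(800)
    d = diagnostics(_fake_draws([x, x.copy()]))
    assert abs(d.loc[0, "rhat"] - 1.0) < 0.01


def test_diagnostics_disjoint_chains(rng):
    """Chains stuck at different constants are flagged as non-converged.
    Rank-normalized split-R-hat saturates near its draw-count-dependent
    ceiling (~1.8 here) rather than diverging to infinity."""
    a = rng.standard_normal(400) * 0.01
    d = diagnostics(_fake_draws([a, a + 50.0]))
    assert d.loc[0, "rhat"] > 1.5


def test_diagnostics_single_chain_warns(rng):
    with pytest.warns(UserWarning, match="single chain"):
        d = diagnostics(_fake_draws([rng.standard_normal(300)]))
    assert np.isnan(d.loc[0, "rhat"])


def test_ar1_effective_sample_size(rng):
    """An AR(1) chain with rho = 0.9 has ESS/N near (1-rho)/(1+rho)."""
    rho, N = 0.9, 20000
    e = rng.standard_normal(N)
    x = np.empty(N)
    x[0] = e[0]
    for i in range(1, N):
        x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * e[i]
    d = diagnostics(_fake_draws([x]))
    ratio = d.loc[0, "ess_bulk"] / N
    target = (1 - rho) / (1 + rho)
    assert target / 2 < ratio < target * 2


def test_trace_data_and_plot(tmp_path, rng):
    fd = _fake_draws([rng.standard_normal(100), rng.standard_normal(100)])
    td = trace_data(fd, "theta")
    assert set(td.columns) == {"chain", "iteration", "value"}
    s = cma_band(rng.standard_normal((200, 20)), grid=np.linspace(0, 1, 20))
    plot_bands(s, path=tmp_path / "bands.png", truth=np.zeros(20))
    assert (tmp_path / "bands.png").exists()
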