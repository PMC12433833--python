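"""Posterior sampling behavior of the fitted models."""

import numpy as np
import pytest

import funbayes as fb
from funbayes import bayes_models as bm
from funbayes.bayes_models import SamplerConfig

FAST = SamplerConfig(chains=1, iterations=500, warmup=220, seed=0)


def test_conjugate_intercept_only_gaussian():
    """Intercept-only Gaussian model with flat priors: the posterior mean
    of the intercept matches the sample mean within Monte-Carlo error."""
    rng = np.random.default_rng(3)
    y = 1.7 + 0.8 * rng.standard_normal(150)
    spec = bm.ModelSpec(family="gaussian", Xr=np.zeros((150, 1)),
                        Xf=np.zeros((150, 0)), y=y,
                        sampler=SamplerConfig(chains=2, iterations=1200,
                                              warmup=400, seed=1))
    draws = bm.fit(spec)
    e0 = draws.stacked("eta0")
    mcse = e0.std() / np.sqrt(len(e0) / 10)  # conservative ESS deflation
    assert abs(e0.mean() - y.mean()) < 3 * max(mcse, 1e-3)


def test_fit_is_seed_deterministic(sofr_data, centered_basis):
    fr1 = fb.fit_sofr(sofr_data, centered_basis, family="gaussian",
                      sampler=FAST)
    fr2 = fb.fit_sofr(sofr_data, centered_basis, family="gaussian",
                      sampler=FAST)
    assert np.array_equal(fr1.draws.params["br"], fr2.draws.params["br"])


def test_draw_shapes_and_diagnostics(sofr_data, centered_basis):
    cfg = SamplerConfig(chains=2, iterations=300, warmup=150, seed=5)
    fr = fb.fit_sofr(sofr_data, centered_basis, family="gaussian",
                     sampler=cfg)
    d = fr.draws
    assert d.params["br"].shape == (2, 150, centered_basis.K0)
    assert d.params["sigma_b2"].shape == (2, 150)
    assert np.all(d.stacked("sigma_b2") > 0)
    assert d.divergences.shape == (2,)
    tidy = d.to_tidy()
    assert set(tidy.columns) == {"chain", "draw", "parameter", "value"}


def test_reparam_and_direct_penalty_posteriors_agree(centered_basis):
    """Fitting through the spectral reparametrization and through the
    explicit b^T S b penalty are the same model: their posterior bands for
    beta(t) overlap everywhere on a fixed small problem."""
    data = fb.simulate_sofr(fb.DGPConfig(n=80, tau=5, seed=21, holdout=5))
    cfg = SamplerConfig(chains=1, iterations=1500, warmup=500, seed=2)
    fr_rep = fb.fit_sofr(data, centered_basis, family="gaussian", sampler=cfg)
    fr_dir = fb.fit_sofr(data, centered_basis, family="gaussian", sampler=cfg,
                         penalty="direct")
    bd_rep = fb.reconstruct_beta(fr_rep.draws, fr_rep.rd, centered_basis)
    bd_dir = fb.reconstruct_beta_direct(fr_dir.draws.stacked("b"),
                                        centered_basis)
    s_rep = fb.cma_band(bd_rep, grid=data.grid)
    s_dir = fb.cma_band(bd_dir, grid=data.grid)
    # 95% pointwise intervals overlap at every grid point
    assert np.all(s_rep.pointwise_lo <= s_dir.pointwise_hi)
    assert np.all(s_dir.pointwise_lo <= s_rep.pointwise_hi)
    # and point estimates are close on the scale of the posterior sd
    assert np.all(np.abs(s_rep.beta_hat - s_dir.beta_hat)
                  <= 4 * np.maximum(s_rep.sd_hat, 1e-6))


def test_cox_simplex_draws_and_hazard(survival_data, centered_basis):
    fr = fb.fit_cox(survival_data, centered_basis, sampler=FAST)
    c = fr.draws.stacked("c")
    assert np.all(c >= 0)
    assert np.abs(c.sum(axis=1) - 1).max() < 1e-8


def test_zero_signal_bands_cover_zero(centered_basis):
    """Under a null signal (tau = 0) the pointwise 95% bands should cover
    zero at most grid points, on average over replicates."""
    fractions = []
    for s in range(5):
        data = fb.simulate_sofr(fb.DGPConfig(n=100, tau=0.0, seed=60 + s,
                                             holdout=5))
        fr = fb.fit_sofr(data, centered_basis, family="gaussian",
                         sampler=SamplerConfig(chains=1, iterations=900,
                                               warmup=350, seed=s))
        bd = fb.reconstruct_beta(fr.draws, fr.rd, centered_basis)
        bands = fb.cma_band(bd, grid=data.grid)
        fractions.append(np.mean(bands.contains(np.zeros(50))))
    assert np.mean(fractions) >= 0.90


def test_fosr_marginal_and_explicit_models_agree():
    """The marginalized FoSR sampler targets the same posterior as the
    explicit-score formulation: coefficient-curve bands from both overlap
    on a fixed small problem."""
    fd = fb.simulate_fosr(fb.DGPConfig(n=60, tau=2, seed=31))
    basis = fb.build_penalized_basis(fd.grid, K=8)
    Xs = fd.X[:, None]
    coef = np.linalg.lstsq(Xs, fd.Y, rcond=None)[0]
    fp = fb.fpca_fit(fd.Y - Xs @ coef, J=3, smooth=False, center=False)
    cfg = SamplerConfig(chains=1, iterations=1500, warmup=600, seed=4)
    fr_m = fb.fit_fosr(fd.Y, Xs, basis, fp.Phi, sampler=cfg)
    fr_e = fb.fit_fosr(fd.Y, Xs, basis, fp.Phi, sampler=cfg,
                       fosr_marginalize=False)
    for fr in (fr_m, fr_e):
        assert fr.draws.params["xi"].shape[-1] == 3
    bm_ = fb.reconstruct_beta_direct(fr_m.draws.stacked("b")[:, 0, :], basis)
    be_ = fb.reconstruct_beta_direct(fr_e.draws.stacked("b")[:, 0, :], basis)
    sm = fb.cma_band(bm_, grid=fd.grid)
    se = fb.cma_band(be_, grid=fd.grid)
    assert np.all(sm.pointwise_lo <= se.pointwise_hi)
    assert np.all(se.pointwise_lo <= sm.pointwise_hi)
    assert np.all(np.abs(sm.beta_hat - se.beta_hat)
                  <= 5 * np.maximum(sm.sd_hat, 1e-8))


def test_divergence_warning_is_nonfatal(monkeypatch, sofr_data,
                                        centered_basis):
    from funbayes import samplers as sam
    orig = sam.nuts_sample

    def noisy(*a, **k):
        res = orig(*a, **k)
        res.divergences = res.draws.shape[0]  # pretend everything diverged
        return res

    monkeypatch.setattr(sam, "nuts_sample", noisy)
    with pytest.warns(RuntimeWarning, match="divergent"):
        fb.fit_sofr(sofr_data, centered_basis, family="gaussian",
                    sampler=FAST)
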