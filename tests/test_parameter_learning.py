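"""Local and Bayesian copula estimation: recovery, diagnostics, PPC,
family selection."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from dcbnet.copula_core import CopulaParams, copula_density, get_family, sample_copula
from dcbnet import parameter_learning as pl


def draw(family, theta, n=2000, seed=0):
    return sample_copula(CopulaParams(family, theta), n, seed)


# -- edge_loglik -----------------------------------------------------------

def test_edge_loglik_independence_is_zero():
    uv = draw("independence", (), 200, 1)
    assert pl.edge_loglik(uv[:, 0], uv[:, 1], CopulaParams("independence", ())) == 0.0


def test_edge_loglik_pointwise_oracle_and_weights():
    """Gaussian ρ=0.5 on 3 hand-picked pairs equals the sum of per-point log
    densities; uniform weight 2 doubles it."""
    params = CopulaParams("gaussian", (0.5,))
    u = np.array([0.2, 0.5, 0.9])
    v = np.array([0.3, 0.6, 0.8])
    expected = sum(np.log(copula_density(params, ui, vi))
                   for ui, vi in zip(u, v))
    assert pl.edge_loglik(u, v, params) == pytest.approx(expected, abs=1e-12)
    assert pl.edge_loglik(u, v, params, weights=np.full(3, 2.0)) == \
        pytest.approx(2 * expected, abs=1e-12)


def test_edge_loglik_permutation_invariance():
    uv = draw("clayton", (2.0,), 500, 3)
    params = CopulaParams("clayton", (2.0,))
    base = pl.edge_loglik(uv[:, 0], uv[:, 1], params)
    perm = np.random.default_rng(0).permutation(500)
    assert pl.edge_loglik(uv[perm, 0], uv[perm, 1], params) == \
        pytest.approx(base, abs=1e-9)


# -- local_fit -------------------------------------------------------------

def test_local_fit_recovers_clayton_theta():
    """Clayton θ=2 data at n=2000: θ̂ in [1.7, 2.3] in >= 9/10 seeds."""
    inside = 0
    for seed in range(10):
        uv = draw("clayton", (2.0,), 2000, seed)
        params, ll = pl.local_fit(uv[:, 0], uv[:, 1], "clayton", restarts=5,
                                  seed=seed)
        inside += 1.7 <= params.theta[0] <= 2.3
    assert inside >= 9


def test_local_fit_independence_and_restart_monotonicity():
    uv = draw("gumbel", (2.0,), 800, 4)
    p, ll = pl.local_fit(uv[:, 0], uv[:, 1], "independence", restarts=1, seed=0)
    assert p.theta == () and ll == 0.0
    _, ll1 = pl.local_fit(uv[:, 0], uv[:, 1], "roch_alegre", restarts=1, seed=2)
    _, ll20 = pl.local_fit(uv[:, 0], uv[:, 1], "roch_alegre", restarts=20, seed=2)
    assert ll20 >= ll1 - 1e-9
    with pytest.raises(ValueError, match="10 observations"):
        pl.local_fit(uv[:5, 0], uv[:5, 1], "clayton")


# -- mcmc_fit --------------------------------------------------------------

def test_mcmc_coverage_gaussian():
    """95% CrI contains the generating ρ=0.6 in >= 9/10 seeds."""
    hits = 0
    for seed in range(10):
        uv = draw("gaussian", (0.6,), 2000, 500 + seed)
        _, s = pl.mcmc_fit(uv[:, 0], uv[:, 1], "gaussian", n_chains=4,
                           n_draws=600, n_adapt=400, seed=seed)
        lo, hi = s["cri_95"][0]
        hits += lo <= 0.6 <= hi
    assert hits >= 9


def test_mcmc_diagnostics_and_local_agreement():
    """Well-identified Clayton data: R̂ < 1.01, local estimate inside the
    95% CrI, and |τ_local − τ_mcmc| <= 0.02."""
    fam = get_family("clayton")
    uv = draw("clayton", (2.0,), 2000, 77)
    p_loc, _ = pl.local_fit(uv[:, 0], uv[:, 1], "clayton", restarts=10, seed=0)
    _, s = pl.mcmc_fit(uv[:, 0], uv[:, 1], "clayton", n_chains=4,
                       n_draws=2000, n_adapt=1000, seed=0)
    d = s["diagnostics"]
    assert d.converged and np.all(d.rhat < 1.01)
    assert 0.05 <= d.acceptance_rate <= 0.95
    lo, hi = s["cri_95"][0]
    assert lo <= p_loc.theta[0] <= hi
    assert abs(fam.tau(p_loc.theta) - fam.tau(s["median"])) <= 0.02


def test_identical_chains_give_unit_rhat():
    """Two chains run from identical states (zero between-chain variance)
    have classic Gelman–Rubin R̂ of exactly 1."""
    uv = draw("gaussian", (0.5,), 500, 3)
    draws, _ = pl.mcmc_fit(uv[:, 0], uv[:, 1], "gaussian", n_chains=2,
                           n_draws=300, n_adapt=200, seed=9)
    dup = np.concatenate([draws[:1], draws[:1]], axis=0)
    assert pl.classic_rhat(dup)[0] == 1.0
    # distinct chains from one converged run stay near 1 as well
    assert pl.classic_rhat(draws)[0] == pytest.approx(1.0, abs=0.05)


def test_mcmc_argument_validation():
    uv = draw("gaussian", (0.5,), 100, 1)
    with pytest.raises(ValueError, match="chains"):
        pl.mcmc_fit(uv[:, 0], uv[:, 1], "gaussian", n_chains=1)
    with pytest.raises(ValueError, match="independence"):
        pl.mcmc_fit(uv[:, 0], uv[:, 1], "independence")


# -- posterior predictive τ check ------------------------------------------

@pytest.fixture(scope="module")
def gaussian_posterior():
    uv = draw("gaussian", (0.55,), 1500, 21)
    draws, _ = pl.mcmc_fit(uv[:, 0], uv[:, 1], "gaussian", n_chains=2,
                           n_draws=500, n_adapt=300, seed=2)
    tau_obs = kendalltau(uv[:, 0], uv[:, 1]).statistic
    return draws, tau_obs


def test_ppc_tau_calibration(gaussian_posterior):
    """Well-specified model: observed τ inside the predictive interval in
    >= 95% of seeds."""
    draws, tau_obs = gaussian_posterior
    passes = sum(
        pl.ppc_tau(draws, "gaussian", n_rep=100, n_obs=400,
                   observed_tau=tau_obs, seed=s)["pass"]
        for s in range(20))
    assert passes >= 19


def test_ppc_tau_power_and_validation(gaussian_posterior):
    draws, tau_obs = gaussian_posterior
    off = pl.ppc_tau(draws, "gaussian", n_rep=100, n_obs=400,
                     observed_tau=tau_obs - 0.5, seed=0)
    assert not off["pass"]
    with pytest.raises(ValueError, match="n_rep"):
        pl.ppc_tau(draws, "gaussian", n_rep=0, n_obs=100, observed_tau=0.0)


# -- posterior medians recover generator tau --------------------------------

@pytest.mark.parametrize("family,tau_target", [
    ("gaussian", 0.45), ("clayton", 0.45), ("joe", 0.45), ("amh", 0.25),
    ("raftery", 0.45),
])
def test_posterior_median_tau_recovery(family, tau_target):
    """Posterior-median τ-equivalents within ±0.05 of generator τ at n=2000."""
    fam = get_family(family)
    theta = fam.theta_from_tau(tau_target).theta
    uv = sample_copula(CopulaParams(family, theta), 2000, 1234)
    _, s = pl.mcmc_fit(uv[:, 0], uv[:, 1], family, n_chains=4, n_draws=600,
                       n_adapt=400, seed=5)
    assert abs(fam.tau(s["median"]) - tau_target) <= 0.05


def test_export_draws_layout(gaussian_posterior):
    draws, _ = gaussian_posterior
    frame = pl.export_draws(draws)
    chains, n, p = np.asarray(draws).shape
    assert len(frame) == chains * n * p
    assert list(frame.columns) == ["chain", "draw", "parameter", "value"]
    sub = frame[(frame["chain"] == 0) & (frame["parameter"] == "theta1")]
    assert np.allclose(sub["value"].to_numpy(), np.asarray(draws)[0, :, 0])


# -- family selection ------------------------------------------------------

def test_select_family_recovers_gumbel():
    """Gumbel θ=2 data against {gumbel, clayton, frank, gaussian}: Gumbel
    ranked first by AIC in >= 8/10 seeds."""
    wins = 0
    for seed in range(10):
        uv = draw("gumbel", (2.0,), 2000, 600 + seed)
        ranked = pl.select_family(uv[:, 0], uv[:, 1],
                                  ["gumbel", "clayton", "frank", "gaussian"],
                                  criterion="aic", restarts=3, seed=seed)
        wins += ranked[0]["family"] == "gumbel"
    assert wins >= 8


def test_select_family_independence_wins_by_bic():
    """Independent data: the 0-parameter independence family ranks first by
    BIC in >= 9/10 seeds (penalty argument)."""
    wins = 0
    for seed in range(10):
        uv = draw("independence", (), 2000, 700 + seed)
        ranked = pl.select_family(uv[:, 0], uv[:, 1],
                                  ["independence", "gaussian", "frank"],
                                  criterion="bic", restarts=3, seed=seed)
        wins += ranked[0]["family"] == "independence"
    assert wins >= 9


def test_select_family_edge_cases():
    uv = draw("gaussian", (0.3,), 300, 2)
    only = pl.select_family(uv[:, 0], uv[:, 1], ["frank"], criterion="loglik")
    assert only[0]["family"] == "frank"
    with pytest.raises(ValueError, match="non-empty"):
        pl.select_family(uv[:, 0], uv[:, 1], [])
    with pytest.raises(ValueError, match="criterion"):
        pl.select_family(uv[:, 0], uv[:, 1], ["frank"], criterion="loo")
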