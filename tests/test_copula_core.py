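"""Copula family contract tests: Sklar boundaries, density/CDF consistency,
τ↔θ maps, conditional sampling."""

import json

import numpy as np
import pytest
from scipy.stats import kendalltau, kstest

from dcbnet import copula_core as cc
from conftest import FAMILY_SETTINGS

ALL_FAMILIES = sorted(FAMILY_SETTINGS)
ONE_PARAM = [f for f in ALL_FAMILIES if cc.get_family(f).n_params == 1]


def mid_setting(name):
    return FAMILY_SETTINGS[name][1]


# -- CDF: boundaries and monotone structure --------------------------------

@pytest.mark.parametrize("name", ALL_FAMILIES)
def test_sklar_boundary_conditions(name):
    """C(u,0)=C(0,v)=0 and uniform margins C(u,1)=u, C(1,v)=v at random
    interior points, for every registered family."""
    fam = cc.get_family(name)
    rng = np.random.default_rng(7)
    for theta in FAMILY_SETTINGS[name]:
        u = rng.uniform(0.01, 0.99, size=100)
        assert np.allclose(fam.cdf(u, np.zeros_like(u), theta), 0.0)
        assert np.allclose(fam.cdf(np.zeros_like(u), u, theta), 0.0)
        assert np.allclose(fam.cdf(u, np.ones_like(u), theta), u, atol=1e-12)
        assert np.allclose(fam.cdf(np.ones_like(u), u, theta), u, atol=1e-12)


@pytest.mark.parametrize("name", ALL_FAMILIES)
def test_cdf_two_increasing(name):
    """C-volume of random rectangles is non-negative (2-increasing)."""
    fam = cc.get_family(name)
    rng = np.random.default_rng(21)
    theta = mid_setting(name)
    a = rng.uniform(0.01, 0.98, size=(200, 2))
    b = a + rng.uniform(0.005, 0.99, size=(200, 2)) * (0.99 - a)
    vol = (fam.cdf(b[:, 0], b[:, 1], theta) - fam.cdf(b[:, 0], a[:, 1], theta)
           - fam.cdf(a[:, 0], b[:, 1], theta) + fam.cdf(a[:, 0], a[:, 1], theta))
    assert np.all(vol >= -1e-10)


def test_uniform_margin_example():
    assert cc.copula_cdf(cc.CopulaParams("joe", (2.0,)), 0.37, 1.0) == pytest.approx(0.37)
    assert cc.copula_cdf(cc.CopulaParams("independence", ()), 0.5, 0.5) == pytest.approx(0.25)


def test_clayton_cdf_closed_form():
    """Clayton C(u,v) = (u^-θ + v^-θ − 1)^(−1/θ) evaluated independently."""
    th = 2.0
    for u, v in [(0.5, 0.5), (0.3, 0.7), (0.9, 0.2)]:
        expected = (u ** -th + v ** -th - 1.0) ** (-1.0 / th)
        got = cc.copula_cdf(cc.CopulaParams("clayton", (th,)), u, v)
        assert got == pytest.approx(expected, abs=1e-12)


# -- density vs finite-difference mixed partial ----------------------------

@pytest.mark.parametrize("name", ALL_FAMILIES)
def test_density_matches_cdf_mixed_partial(name):
    """c(u,v) agrees with the central-difference ∂²C/∂u∂v within 1e-4 on a
    21x21 interior grid (grids chosen off the u=v diagonal and off the
    Marshall-Olkin singular curve, where the density is a.e.-defined only)."""
    fam = cc.get_family(name)
    gu = np.linspace(0.06, 0.94, 21)
    gv = np.linspace(0.052, 0.948, 21)  # avoids exact u = v crossings
    U, V = np.meshgrid(gu, gv)
    eps = 1e-5
    for theta in FAMILY_SETTINGS[name]:
        fd = (fam.cdf(U + eps, V + eps, theta) - fam.cdf(U + eps, V - eps, theta)
              - fam.cdf(U - eps, V + eps, theta)
              + fam.cdf(U - eps, V - eps, theta)) / (4 * eps * eps)
        pdf = fam.pdf(U, V, theta)
        mask = np.abs(U - V) > 10 * eps
        if name == "marshall_olkin":
            a, b = theta
            mask &= np.abs(U ** a - V ** b) > 0.02
        assert np.max(np.abs(fd[mask] - pdf[mask])) < 1e-4


def test_independence_density_flat():
    p = cc.CopulaParams("independence", ())
    assert cc.copula_density(p, 0.3, 0.8) == pytest.approx(1.0)
    assert cc.copula_density(cc.CopulaParams("gaussian", (0.0,)), 0.3, 0.8) == pytest.approx(1.0)


@pytest.mark.parametrize("name", ["gaussian", "clayton", "frank", "joe", "amh",
                                  "raftery", "roch_alegre"])
def test_density_integrates_to_one(name):
    """∫∫ c du dv = 1 for absolutely continuous families (coarse grid)."""
    fam = cc.get_family(name)
    theta = mid_setting(name)
    g = np.linspace(0.5 / 400, 1 - 0.5 / 400, 400)
    U, V = np.meshgrid(g, g)
    total = fam.pdf(U, V, theta).mean()
    assert total == pytest.approx(1.0, abs=0.02)


def test_marshall_olkin_singular_mass():
    """The MO density integrates to 1 − τ: the missing mass sits on the
    singular curve u^θ1 = v^θ2."""
    fam = cc.get_family("marshall_olkin")
    theta = (0.5, 0.7)
    g = np.linspace(0.5 / 600, 1 - 0.5 / 600, 600)
    U, V = np.meshgrid(g, g)
    total = fam.pdf(U, V, theta).mean()
    assert total == pytest.approx(1.0 - fam.tau(theta), abs=0.02)


# -- h-function ------------------------------------------------------------

@pytest.mark.parametrize("name", ALL_FAMILIES)
def test_hfunc_is_conditional_cdf(name):
    """h(v|u) is non-decreasing in v with h(0|u)=0, h(1|u)=1, and matches the
    central-difference ∂C/∂u away from kinks."""
    fam = cc.get_family(name)
    theta = mid_setting(name)
    u = 0.37
    v = np.linspace(0.01, 0.99, 50)
    h = fam.hfunc(v, np.full_like(v, u), theta)
    assert np.all(np.diff(h) >= -1e-10)
    assert fam.hfunc(0.0, u, theta) == pytest.approx(0.0)
    assert fam.hfunc(1.0, u, theta) == pytest.approx(1.0)
    eps = 1e-6
    fd = (fam.cdf(u + eps, v, theta) - fam.cdf(u - eps, v, theta)) / (2 * eps)
    mask = np.abs(v - u) > 1e-3
    if name == "marshall_olkin":
        a, b = theta
        mask &= np.abs(u ** a - v ** b) > 0.02
    assert np.max(np.abs(h[mask] - fd[mask])) < 1e-4


def test_hfunc_independence_and_clayton_oracle():
    v = np.linspace(0.05, 0.95, 11)
    assert np.allclose(cc.conditional_cdf(cc.CopulaParams("independence", ()), v, 0.42), v)
    # Clayton closed form: h(v|u) = u^{-θ-1} (u^-θ + v^-θ − 1)^{-1/θ − 1}
    th = 2.0
    expected = 0.5 ** (-th - 1) * (0.5 ** -th + 0.5 ** -th - 1) ** (-1 / th - 1)
    got = cc.conditional_cdf(cc.CopulaParams("clayton", (th,)), 0.5, 0.5)
    assert got == pytest.approx(expected, abs=1e-10)


# -- sampling --------------------------------------------------------------

@pytest.mark.parametrize("name", ALL_FAMILIES)
def test_sampling_margins_and_tau(name):
    """Sampled pairs have uniform margins (KS) and empirical τ within 3 SE
    of the population value, at two parameter settings each."""
    fam = cc.get_family(name)
    n = 10_000
    for k, theta in enumerate(FAMILY_SETTINGS[name][:2]):
        uv = fam.sample(n, theta, np.random.default_rng(100 + k))
        assert kstest(uv[:, 0], "uniform").pvalue > 0.01
        assert kstest(uv[:, 1], "uniform").pvalue > 0.01
        emp = kendalltau(uv[:, 0], uv[:, 1]).statistic
        se = 3 * np.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        assert abs(emp - fam.tau(theta)) < se


def test_sampling_deterministic_and_null():
    p = cc.CopulaParams("independence", ())
    a = cc.sample_copula(p, 1000, 5)
    b = cc.sample_copula(p, 1000, 5)
    assert np.array_equal(a, b)
    big = cc.sample_copula(p, 10_000, 6)
    assert abs(kendalltau(big[:, 0], big[:, 1]).statistic) < 0.03


def test_gaussian_sampling_matches_greiner_tau():
    """Gaussian ρ=0.9: empirical τ near (2/π)·arcsin(0.9)."""
    p = cc.CopulaParams("gaussian", (0.9,))
    uv = cc.sample_copula(p, 10_000, 9)
    expected = 2 / np.pi * np.arcsin(0.9)
    assert abs(kendalltau(uv[:, 0], uv[:, 1]).statistic - expected) < 0.03


# -- Kendall tau maps ------------------------------------------------------

def test_closed_form_taus():
    assert cc.tau_from_theta(cc.CopulaParams("clayton", (2.0,))) == pytest.approx(0.5)
    assert cc.tau_from_theta(cc.CopulaParams("gaussian", (0.0,))) == pytest.approx(0.0)
    assert cc.tau_from_theta(cc.CopulaParams("raftery", (0.6,))) == pytest.approx(0.5)
    assert cc.tau_from_theta(cc.CopulaParams("gumbel", (2.0,))) == pytest.approx(0.5)
    # AMH closed form 1 − 2(θ+(1−θ)² ln(1−θ))/(3θ²)
    th = 0.5
    expected = 1 - 2 * (th + (1 - th) ** 2 * np.log(1 - th)) / (3 * th * th)
    assert cc.tau_from_theta(cc.CopulaParams("amh", (th,))) == pytest.approx(expected)
    # Marshall-Olkin θ1θ2/(θ1+θ2−θ1θ2)
    assert cc.tau_from_theta(cc.CopulaParams("marshall_olkin", (0.5, 0.7))) == \
        pytest.approx(0.5 * 0.7 / (0.5 + 0.7 - 0.35))


@pytest.mark.parametrize("name", ["joe", "roch_alegre"])
def test_numeric_tau_against_monte_carlo(name):
    """Generator-integral/series τ cross-checked by large-n sampling."""
    fam = cc.get_family(name)
    theta = mid_setting(name)
    uv = fam.sample(100_000, theta, np.random.default_rng(17))
    assert abs(fam.tau(theta) - kendalltau(uv[:, 0], uv[:, 1]).statistic) < 0.01


@pytest.mark.parametrize("name", ONE_PARAM)
def test_tau_theta_round_trip(name):
    """τ → θ → τ round trip below 1e-6 over 25 points of the attainable
    range for every one-parameter family."""
    fam = cc.get_family(name)
    lo, hi = fam.tau_range()
    span = hi - lo
    for tau in np.linspace(lo + 0.03 * span, hi - 0.03 * span, 25):
        back = fam.tau(fam.theta_from_tau(tau).theta)
        assert abs(back - tau) < 1e-6


def test_theta_from_tau_examples_and_errors():
    assert cc.theta_from_tau("clayton", 0.5).theta[0] == pytest.approx(2.0)
    assert cc.theta_from_tau("gumbel", 0.0).theta[0] == pytest.approx(1.0)
    joe = cc.theta_from_tau("joe", 0.3)
    assert abs(cc.tau_from_theta(joe) - 0.3) < 1e-6
    with pytest.raises(ValueError, match="range"):
        cc.theta_from_tau("clayton", -0.4)
    with pytest.raises(ValueError, match="attainable"):
        cc.theta_from_tau("amh", 0.9)


# -- validation and registry ----------------------------------------------

def test_domain_and_input_errors():
    with pytest.raises(ValueError, match="domain"):
        cc.CopulaParams("clayton", (-1.0,))
    with pytest.raises(ValueError, match="NaN"):
        cc.copula_cdf(cc.CopulaParams("clayton", (2.0,)), float("nan"), 0.5)
    with pytest.raises(ValueError, match="unit interval"):
        cc.copula_cdf(cc.CopulaParams("clayton", (2.0,)), 1.2, 0.5)
    with pytest.raises(ValueError, match="open"):
        cc.copula_density(cc.CopulaParams("clayton", (2.0,)), 0.0, 0.5)
    with pytest.raises(ValueError, match="parameter"):
        cc.CopulaParams("gaussian", (0.5, 0.2))
    with pytest.raises(KeyError, match="unknown copula family"):
        cc.get_family("vine")


def test_registry_descriptor_round_trip():
    text = cc.registry_descriptor()
    entries = cc.registry_from_descriptor(text)
    names = {e["name"] for e in entries}
    assert {"joe", "amh", "marshall_olkin", "raftery", "roch_alegre",
            "gaussian", "independence", "clayton", "frank", "gumbel"} <= names
    mo = next(e for e in entries if e["name"] == "marshall_olkin")
    assert mo["n_params"] == 2
    bad = json.loads(text)
    bad[0]["n_params"] = 9
    with pytest.raises(ValueError, match="mismatch"):
        cc.registry_from_descriptor(json.dumps(bad))
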