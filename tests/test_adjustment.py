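"""Selection/spillover toolkit: IPW, balance, CPI, block bootstrap."""

import numpy as np
import pandas as pd
import pytest

from dcbnet import adjustment as adj
from dcbnet.dependence import kendall_tau_b
from dcbnet.panel import PanelDataset, VariableSchema
from dcbnet.synthetic_data import baseline_covariates, default_config, generate_panel


# -- stabilized IPW --------------------------------------------------------

def test_ipw_null_confounding_weights_near_one():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"x": rng.normal(size=2000)})
    a = rng.integers(0, 2, size=2000)
    ws = adj.stabilized_ipw(X, a)
    assert np.all(ws.weights > 0)
    assert abs(ws.weights.mean() - 1.0) < 0.1
    assert np.all(np.abs(ws.weights - 1.0) < 0.25)


def test_ipw_two_by_two_hand_oracle():
    """One binary covariate with known cell counts: stabilized weights equal
    marginal/conditional frequency ratios computed by hand."""
    # cells: (x=0,a=0)=40, (x=0,a=1)=10, (x=1,a=0)=20, (x=1,a=1)=30
    x = np.array([0] * 50 + [1] * 50)
    a = np.array([0] * 40 + [1] * 10 + [0] * 20 + [1] * 30)
    ws = adj.stabilized_ipw(pd.DataFrame({"x": x}), a)
    p_a1 = 0.4
    e_x0, e_x1 = 10 / 50, 30 / 50
    expected = np.where(a == 1,
                        p_a1 / np.where(x == 0, e_x0, e_x1),
                        (1 - p_a1) / (1 - np.where(x == 0, e_x0, e_x1)))
    assert np.allclose(ws.weights, expected, atol=1e-6)


def test_ipw_mean_approaches_one_and_truncation():
    rng = np.random.default_rng(3)
    x = rng.normal(size=5000)
    p = 1 / (1 + np.exp(-(0.8 * x - 0.2)))
    a = rng.uniform(size=5000) < p
    ws = adj.stabilized_ipw(pd.DataFrame({"x": x}), a.astype(int))
    assert abs(ws.weights.mean() - 1.0) < 0.05
    trunc = adj.stabilized_ipw(pd.DataFrame({"x": x}), a.astype(int),
                               truncation=(1, 99))
    assert trunc.weights.max() <= ws.weights.max()


def test_ipw_separation_raises():
    x = np.array([0.0] * 20 + [1.0] * 20)
    a = np.array([0] * 20 + [1] * 20)
    with pytest.raises(RuntimeError, match="separation|propensity"):
        adj.stabilized_ipw(pd.DataFrame({"x": x}), a)
    with pytest.raises(ValueError, match="classes"):
        adj.stabilized_ipw(pd.DataFrame({"x": x}), np.ones(40))


# -- balance diagnostics ---------------------------------------------------

def test_balance_smd_basic_cases():
    g = np.array([0] * 50 + [1] * 50)
    same = np.tile(np.arange(50.0), 2)
    out = adj.balance_smd(pd.DataFrame({"c": same}), g)
    assert out.loc["c", "smd"] == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(0)
    shifted = np.concatenate([rng.normal(0, 1, 4000), rng.normal(1, 1, 4000)])
    g2 = np.array([0] * 4000 + [1] * 4000)
    out2 = adj.balance_smd(pd.DataFrame({"c": shifted}), g2)
    assert out2.loc["c", "smd"] == pytest.approx(1.0, abs=0.1)
    assert out2.loc["c", "rank_p"] < 0.01
    const = adj.balance_smd(pd.DataFrame({"c": np.ones(100)}), g)
    assert const.loc["c", "degenerate"]


def test_ipw_improves_balance_on_confounded_panel():
    """Generator-set SMD ≈ 0.18 is recovered within ±0.05 and weighting
    shrinks it (10 seeds)."""
    cfg = default_config(n_units=1500, seed=0)
    improved = 0
    recovered = 0
    for seed in range(10):
        panel = generate_panel(
            default_config(n_units=1500, seed=900 + seed))
        cov, a = baseline_covariates(panel, cfg, target_smd=0.18, seed=seed)
        synth = cov[["household_size", "mother_edu"]]
        before = adj.balance_smd(synth, a, rank_tests=False)
        recovered += abs(abs(before.loc["household_size", "smd"]) - 0.18) < 0.05
        ws = adj.stabilized_ipw(cov, a)
        after = adj.balance_smd(synth, a, weights=ws.weights, rank_tests=False)
        improved += (after["smd"].abs().max() <= before["smd"].abs().max())
    assert recovered >= 8
    assert improved >= 8


# -- CPI -------------------------------------------------------------------

def make_panel(df):
    schema = {"any_program": VariableSchema("any_program", "binary", (0, 1))}
    return PanelDataset(df, schema)


def test_cpi_hand_examples():
    """Community of 5 with 2 other participants: CPI = 0.5; all others
    participating: CPI = 1; singleton community: missing."""
    df = pd.DataFrame({
        "unit": [f"u{i}" for i in range(9)],
        "community": ["a"] * 5 + ["b"] * 3 + ["c"],
        "wave": "2009",
        "any_program": [0, 1, 1, 0, 0] + [1, 1, 1] + [1],
    })
    cpi = adj.cpi_leave_one_out(make_panel(df), "2009", "any_program").frame
    by_unit = cpi.set_index("unit")["cpi"]
    assert by_unit["u0"] == pytest.approx(0.5)  # 2 of 4 others
    assert by_unit["u5"] == pytest.approx(1.0)
    assert np.isnan(by_unit["u8"])
    with pytest.raises(KeyError, match="unknown program indicator"):
        adj.cpi_leave_one_out(make_panel(df), "2009", "psnp")


def test_cpi_matches_brute_force_recount():
    rng = np.random.default_rng(5)
    n = 300
    df = pd.DataFrame({
        "unit": [f"u{i}" for i in range(n)],
        "community": rng.choice(["a", "b", "c"], size=n),
        "wave": "2013",
        "any_program": rng.integers(0, 2, size=n),
    })
    cpi = adj.cpi_leave_one_out(make_panel(df), "2013", "any_program").frame
    for _, row in cpi.iterrows():
        others = df[(df["community"] == row["community"])
                    & (df["unit"] != row["unit"])]
        assert row["cpi"] == pytest.approx(others["any_program"].mean())


# -- community block bootstrap ---------------------------------------------

def test_bootstrap_constant_statistic_and_determinism(study_panel):
    point, ci, reps = adj.community_block_bootstrap(
        study_panel, lambda p: 3.25, B=100, seed=1)
    assert point == 3.25 and ci == (3.25, 3.25)
    _, _, reps2 = adj.community_block_bootstrap(
        study_panel, lambda p: p.df["FS"].mean(), B=100, seed=2)
    _, _, reps3 = adj.community_block_bootstrap(
        study_panel, lambda p: p.df["FS"].mean(), B=100, seed=2)
    assert np.array_equal(reps2, reps3)


def test_bootstrap_ci_covers_generator_tau():
    """Percentile CI for a copula-linked edge τ covers the generator's
    population value (estimated once on a very large panel) in >= 90% of
    trials at reduced B."""

    def stat(p):
        x, y, _, _ = p.pairs("PS", "FS", "2016", "2016")
        return kendall_tau_b(x, y).tau

    target = stat(generate_panel(default_config(n_units=30_000, seed=555)))
    covered = 0
    trials = 20
    for seed in range(trials):
        panel = generate_panel(default_config(n_units=1000, seed=1000 + seed))
        point, (lo, hi), _ = adj.community_block_bootstrap(
            panel, stat, B=120, seed=seed)
        covered += lo <= target <= hi
    assert covered >= trials * 0.9


def test_bootstrap_validation(study_panel):
    with pytest.raises(ValueError, match="B must be"):
        adj.community_block_bootstrap(study_panel, lambda p: 0.0, B=10)

    def flaky(p):
        # fails only on bootstrap replicates (re-keyed communities)
        if p.df["community"].str.contains("#b").any():
            raise RuntimeError("boom")
        return 0.0

    with pytest.raises(RuntimeError, match="failure rate"):
        adj.community_block_bootstrap(study_panel, flaky, B=100, seed=0)
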