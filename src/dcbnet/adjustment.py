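"""Selection-bias and spillover toolkit.

Stabilized inverse-probability-of-treatment weights from baseline (pre-
program) covariates, standardized-mean-difference balance diagnostics with
rank-based tests, the leave-one-out community program intensity (CPI)
spillover proxy, and a community-block bootstrap for uncertainty under
within-community dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["WeightSet", "CPISeries", "stabilized_ipw", "balance_smd",
           "cpi_leave_one_out", "community_block_bootstrap"]


@dataclass
class WeightSet:
    units: np.ndarray
    weights: np.ndarray
    stabilized: bool = True
    truncation: tuple[float, float] | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.units)

    def to_csv(self, path) -> None:
        pd.DataFrame({"unit": self.units, "weight": self.weights}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeightSet":
        df = pd.read_csv(path)
        return cls(df["unit"].to_numpy(), df["weight"].to_numpy())


@dataclass
class CPISeries:
    frame: pd.DataFrame  # unit, wave, community, community_size, cpi

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CPISeries":
        return cls(pd.read_csv(path, dtype={"wave": str}, comment="#"))


def stabilized_ipw(baseline_covariates, participation, truncation=None,
                   units=None) -> WeightSet:
    """Stabilized inverse-probability weights from pre-program covariates.

    Propensity e(X) = P(A=1|X) by main-effects logistic regression; each
    unit's weight is P(A=a)/P(A=a|X) for its observed a, so the weighted
    sample mean stays near 1.  ``truncation=(lo_pct, hi_pct)`` optionally
    clips weights at symmetric percentiles.
    """
    X = pd.DataFrame(baseline_covariates)
    a = np.asarray(participation, dtype=float)
    if len(X) != len(a):
        raise ValueError("covariates and participation must align")
    if not (np.any(a == 0) and np.any(a == 1)):
        raise ValueError("both participation classes must be present")
    design = sm.add_constant(X.to_numpy(dtype=float))
    try:
        fit = sm.GLM(a, design, family=sm.families.Binomial()).fit()
        ps = np.asarray(fit.fittedvalues)
    except Exception as exc:
        raise RuntimeError(f"propensity model failed: {exc}") from exc
    if np.any(ps < 1e-8) or np.any(ps > 1 - 1e-8):
        raise RuntimeError(
            "perfect separation in the propensity model; consider truncating "
            "weights or penalizing the propensity fit")
    p_marg = a.mean()
    w = np.where(a == 1, p_marg / ps, (1 - p_marg) / (1 - ps))
    if truncation is not None:
        lo, hi = np.percentile(w, truncation)
        w = np.clip(w, lo, hi)
    units = np.asarray(units) if units is not None else np.arange(len(a))
    return WeightSet(units=units, weights=w, stabilized=True,
                     truncation=truncation)


def balance_smd(covariates, groups, weights=None, rank_tests: bool = True
                ) -> pd.DataFrame:
    """Per-covariate standardized mean differences (and Wilcoxon rank-sum
    p-values) between two groups, optionally weighted.

    SMD = (mean₁ − mean₀)/pooled SD; the pooled SD is always the unweighted
    one so weighted and unweighted SMDs are on the same scale.  Zero pooled
    SD flags the covariate as degenerate (SMD = NaN).
    """
    X = pd.DataFrame(covariates)
    g = np.asarray(groups, dtype=int)
    if not (np.any(g == 0) and np.any(g == 1)):
        raise ValueError("both groups must be non-empty")
    w = np.ones(len(g)) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        m1 = np.average(x[g == 1], weights=w[g == 1])
        m0 = np.average(x[g == 0], weights=w[g == 0])
        v1 = np.var(x[g == 1], ddof=1)
        v0 = np.var(x[g == 0], ddof=1)
        pooled = np.sqrt(0.5 * (v1 + v0))
        smd = (m1 - m0) / pooled if pooled > 0 else float("nan")
        row = {"covariate": col, "smd": smd, "degenerate": pooled == 0}
        if rank_tests:
            row["rank_p"] = float(
                stats.mannwhitneyu(x[g == 1], x[g == 0],
                                   alternative="two-sided").pvalue)
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")


def cpi_leave_one_out(panel, wave, program_indicator: str) -> CPISeries:
    """Leave-one-out community program intensity.

    For unit i in community g of size n_g at the given wave,
    CPI = (# participating households in g excluding i)/(n_g − 1);
    missing (NaN) for singleton communities.  ``program_indicator`` is a
    binary 0/1 column (e.g. "participation in any initiative").
    """
    frame = panel.wave_frame(wave)
    if program_indicator not in frame.columns:
        raise KeyError(f"unknown program indicator {program_indicator!r}")
    a = frame[program_indicator].to_numpy(dtype=float)
    comm = frame["community"].to_numpy()
    totals = frame.groupby("community")[program_indicator].transform("sum").to_numpy(dtype=float)
    sizes = frame.groupby("community")[program_indicator].transform("size").to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cpi = (totals - a) / (sizes - 1.0)
    cpi = np.where(sizes > 1, cpi, np.nan)
    out = pd.DataFrame({
        "unit": frame["unit"].to_numpy(),
        "wave": wave,
        "community": comm,
        "community_size": sizes.astype(int),
        "cpi": cpi,
    })
    return CPISeries(out)


def community_block_bootstrap(panel, statistic, B: int = 200, seed: int = 0,
                              max_failure_rate: float = 0.10):
    """Community-block bootstrap: resample communities with replacement,
    keep all units of each sampled community, recompute ``statistic``
    (a callable taking a panel-like object and returning a float).

    Returns (point estimate, (lo, hi) percentile 95% CI, replicate values).
    Replicates where the statistic fails are dropped with a logged count; a
    failure rate above ``max_failure_rate`` is a hard error.
    """
    from .panel import PanelDataset

    if B < 100:
        raise ValueError("B must be >= 100")
    communities = np.asarray(sorted(panel.df["community"].unique()))
    if len(communities) < 2:
        raise ValueError("need at least 2 communities")
    rng = np.random.default_rng(seed)
    point = float(statistic(panel))
    reps = []
    failures = 0
    groups = {c: panel.df[panel.df["community"] == c] for c in communities}
    for b in range(B):
        sampled = rng.choice(communities, size=len(communities), replace=True)
        parts = []
        for k, c in enumerate(sampled):
            sub = groups[c].copy()
            # re-key units/communities so duplicated blocks stay distinct
            sub["community"] = f"{c}#b{k}"
            sub["unit"] = sub["unit"].astype(str) + f"#b{k}"
            parts.append(sub)
        bdf = pd.concat(parts, ignore_index=True)
        bpanel = PanelDataset(bdf, panel.schema, list(panel.waves))
        try:
            reps.append(float(statistic(bpanel)))
        except Exception as exc:
            failures += 1
            log.debug("bootstrap replicate %d failed: %s", b, exc)
    if failures:
        log.info("community_block_bootstrap: %d/%d replicates failed",
                 failures, B)
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"bootstrap failure rate {failures}/{B} exceeds "
            f"{max_failure_rate:.0%}")
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi)), reps
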