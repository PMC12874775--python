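"""Tie-corrected Kendall rank correlation (τ-b) and per-wave edge trajectories.

τ-b is the dependence summary used throughout the network: it is rank-based,
invariant to monotone transformations, robust to ties in ordinal/binary
household measures, and maps in closed form to copula parameters for many
families.  The weighted variant uses pairwise weight products with weighted
tie corrections and reduces exactly to τ-b at unit weights; its significance
is left to the community-block bootstrap (see :mod:`dcbnet.adjustment`)
because observation weights invalidate the normal-approximation variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TauEstimate", "kendall_tau_b", "tau_trajectory", "trajectory_table",
           "significance_stars"]


@dataclass(frozen=True)
class TauEstimate:
    tau: float
    n_pairs: int
    z_stat: float
    p_value: float
    weighted: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Footnote convention: * 10%, ** 5%, *** 1%."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def kendall_tau_b(x, y, weights=None) -> TauEstimate:
    """Kendall τ-b between two vectors, optionally observation-weighted.

    The estimator sums sign products over all pairs (i, j), each pair carrying
    weight w_i·w_j, with weighted tie corrections in the denominator:

        τ = Σ w_ij sgn(xj−xi) sgn(yj−yi) / sqrt((T − Tx)(T − Ty))

    where T = Σ w_ij over pairs and Tx, Ty are the tied-pair weight sums.
    Significance (unweighted case) uses the normal approximation
    z = 3τ √(n(n−1)) / √(2(2n+5)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("degenerate input: constant vector has undefined tau")
    weighted = weights is not None
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match data length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")

    num = 0.0
    T = Tx = Ty = 0.0
    chunk = 512
    cols = np.arange(n)[None, :]
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        dx = np.sign(x[i0:i1, None] - x[None, :])
        dy = np.sign(y[i0:i1, None] - y[None, :])
        ww = w[i0:i1, None] * w[None, :]
        upper = cols > np.arange(i0, i1)[:, None]  # count each pair once
        ww = ww * upper
        num += float(np.sum(ww * dx * dy))
        T += float(np.sum(ww))
        Tx += float(np.sum(ww * (dx == 0)))
        Ty += float(np.sum(ww * (dy == 0)))
    denom = np.sqrt((T - Tx) * (T - Ty))
    if denom == 0:
        raise ValueError("degenerate input: tie correction removed all pairs")
    tau = num / denom

    if weighted:
        z, p = float("nan"), float("nan")
    else:
        z = 3.0 * tau * np.sqrt(n * (n - 1)) / np.sqrt(2.0 * (2 * n + 5))
        p = 2.0 * stats.norm.sf(abs(z))
    return TauEstimate(float(tau), int(n * (n - 1) // 2), float(z), float(p),
                       weighted)


def tau_trajectory(panel, edge, waves, weights=None, lag: int | None = None):
    """Per-wave τ estimates for a network edge.

    ``edge`` is an ordered pair (x, y).  For contemporaneous edges (lag 0) τ
    is computed on complete (x, y) pairs within each wave.  Self-loop edges
    (x == y, or lag=1) pair the value at wave t with the value at wave t+1
    for units observed in both; the result is keyed "t -> t+1".
    """
    x, y = edge

    def _resolve_w(wcol, units):
        if weights is None:
            return None
        if isinstance(weights, str) and weights == "panel":
            return wcol
        w = pd.Series(weights)  # mapping / Series keyed by unit id
        return w.reindex(units).to_numpy()

    if lag is None:
        lag = 1 if x == y else 0
    missing = [w for w in waves if w not in set(panel.df["wave"])]
    if missing:
        raise KeyError(f"waves {missing} not present in panel")
    if lag == 1 and len(waves) < 2:
        raise ValueError(
            f"self-loop/lagged edge {x} -> {y} needs at least 2 waves")
    out: dict[str, TauEstimate] = {}
    if lag == 0:
        for wv in waves:
            xs, ys, wcol, units = panel.pairs(x, y, wv, wv)
            out[str(wv)] = kendall_tau_b(xs, ys, _resolve_w(wcol, units))
    else:
        for w0, w1 in zip(waves[:-1], waves[1:]):
            xs, ys, wcol, units = panel.pairs(x, y, w0, w1)
            out[f"{w0} -> {w1}"] = kendall_tau_b(xs, ys, _resolve_w(wcol, units))
    return out


def trajectory_table(panel, edges, waves, weights=None) -> pd.DataFrame:
    """Edge × wave table of 'τ with stars' strings, mirroring the standard
    per-wave dependence report layout.  Exportable with ``to_csv``."""
    rows = []
    for edge in edges:
        traj = tau_trajectory(panel, edge, waves, weights=weights)
        row = {"edge": f"{edge[0]} -> {edge[1]}"}
        for key, est in traj.items():
            row[key] = f"{est.tau:.3f}{est.stars}"
        rows.append(row)
    return pd.DataFrame(rows)
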