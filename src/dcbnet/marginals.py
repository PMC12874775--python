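"""Per-node marginal models and pseudo-uniform transforms.

Copula conditionals act on uniform scores, so every observed variable must
first be pushed through its marginal CDF.  Continuous variables use the
probability integral transform (PIT) with an n/(n+1)-rescaled empirical CDF;
discrete/ordinal variables use the distributional transform
U = F(x−) + V·(F(x) − F(x−)), V ~ Uniform(0,1), which resolves ties and
yields exactly uniform pseudo-observations when the model is correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

DISCRETE_SCALES = ("binary", "ordinal", "categorical")
SCALES = DISCRETE_SCALES + ("continuous",)


@dataclass
class MarginalModel:
    """Marginal distribution of one node at one (or a pooled set of) slice(s).

    For discrete scales ``levels``/``probs`` give the category masses and
    ``cdf``/``cdf_minus`` the right/left cumulative limits per level.  For
    continuous scales the sorted sample defines an empirical CDF rescaled by
    n/(n+1) so transforms never reach exactly 1.
    """

    scale: str
    levels: np.ndarray | None = None
    probs: np.ndarray | None = None
    cdf: np.ndarray | None = None
    cdf_minus: np.ndarray | None = None
    sorted_values: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    @property
    def is_discrete(self) -> bool:
        return self.scale in DISCRETE_SCALES

    def level_interval(self, x):
        """(F(x−), F(x)) for a discrete level x."""
        i = self._index[x]
        return float(self.cdf_minus[i]), float(self.cdf[i])

    def quantile(self, q):
        """Generalized inverse CDF (used by the synthetic generator)."""
        q = np.asarray(q, dtype=float)
        if self.is_discrete:
            idx = np.searchsorted(self.cdf, q, side="left")
            idx = np.clip(idx, 0, len(self.levels) - 1)
            out = self.levels[idx]
            return out
        i = np.clip((q * (len(self.sorted_values) + 1)).astype(int) - 1, 0,
                    len(self.sorted_values) - 1)
        return self.sorted_values[i]

    def logpmf(self, values):
        """Log marginal mass/density of observations (discrete scales only
        contribute to likelihood decomposition; continuous uses a histogram-free
        rank likelihood of zero)."""
        if self.is_discrete:
            idx = np.array([self._index[x] for x in np.asarray(values).ravel()])
            p = np.maximum(self.probs[idx], 1e-300)
            return np.log(p)
        return np.zeros(np.asarray(values).size)


def estimate_marginal(values, scale: str, weights=None) -> MarginalModel:
    """Estimate a marginal model from observations.

    Discrete scales get (weighted) relative-frequency masses over the observed
    (or supplied) support; continuous scales an empirical CDF.  Missing values
    (NaN) are dropped with a logged count.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    values = np.asarray(values)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise ValueError("weights must match values in length")
        if np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError("weights must be non-negative and not all zero")
    if values.dtype.kind == "f":
        keep = ~np.isnan(values)
        if keep.sum() < len(values):
            log.info("estimate_marginal: dropped %d missing values",
                     len(values) - keep.sum())
        values = values[keep]
        if weights is not None:
            weights = weights[keep]
    if values.size == 0:
        raise ValueError("all values missing")

    if scale == "continuous":
        if len(np.unique(values)) < 2:
            raise ValueError("continuous scale needs >= 2 distinct values")
        return MarginalModel(scale=scale, sorted_values=np.sort(values.astype(float)))

    levels = np.unique(values)
    w = np.ones(len(values)) if weights is None else weights
    mass = np.array([w[values == lev].sum() for lev in levels], dtype=float)
    probs = mass / mass.sum()
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    cdf_minus = np.concatenate([[0.0], cdf[:-1]])
    return MarginalModel(
        scale=scale,
        levels=levels,
        probs=probs,
        cdf=cdf,
        cdf_minus=cdf_minus,
        _index={lev: i for i, lev in enumerate(levels)},
    )


def pit_transform(values, model: MarginalModel) -> np.ndarray:
    """Probability integral transform F(x) for a continuous marginal.

    Uses rank/(n+1) against the model's sample so outputs stay in (0, 1).
    """
    if model.is_discrete:
        # F(x) at the level's right limit; ties are NOT resolved — use
        # distributional_transform for copula pseudo-observations.
        out = np.empty(len(values))
        for i, x in enumerate(np.asarray(values).ravel()):
            if x not in model._index:
                raise ValueError(f"value {x!r} outside marginal support")
            out[i] = model.cdf[model._index[x]]
        return out
    values = np.asarray(values, dtype=float)
    sv = model.sorted_values
    lo, hi = sv[0], sv[-1]
    if np.any(values < lo) or np.any(values > hi):
        bad = values[(values < lo) | (values > hi)][0]
        raise ValueError(f"value {bad!r} outside marginal support [{lo}, {hi}]")
    ranks = np.searchsorted(sv, values, side="right")
    return ranks / (len(sv) + 1.0)


def distributional_transform(values, model: MarginalModel, seed) -> np.ndarray:
    """Randomized PIT for discrete data: U = F(x−) + V·(F(x) − F(x−)).

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed seed gives
    a reproducible vector.
    """
    if not model.is_discrete:
        raise TypeError(
            "distributional_transform expects a discrete marginal; "
            "use pit_transform for continuous scales"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values).ravel()
    lo = np.empty(len(values))
    hi = np.empty(len(values))
    for i, x in enumerate(values):
        if x not in model._index:
            raise ValueError(f"value {x!r} outside marginal support")
        lo[i], hi[i] = model.level_interval(x)
    v = rng.uniform(size=len(values))
    return lo + v * (hi - lo)
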