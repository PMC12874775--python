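"""Score-based structure learning for the two-graph dynamic network.

Greedy hill-climbing with add/delete/reverse moves over a constraint
template, scored by the graph-form BIC

    score(G : D) = ℓ(D : θ̂, G) − 0.5·log(K)·|Θ_G|,

where ℓ is the maximized edge-wise copula log-likelihood plus the (graph-
independent) marginal log-likelihoods, K is the number of sequences when
learning the initial graph G0 and the total number of transitions when
learning the transition graph G→, and |Θ_G| counts free copula parameters.
Decomposability over edges lets the two parts be learned separately and
makes move evaluation a cached per-edge lookup.

Because bivariate copula likelihoods are symmetric in their arguments, edge
direction is supplied by the constraint template (the field's orientation
conventions), not inferred from data; a reverse move is admitted only when
the reversed edge is itself in the template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamic_graph import DynamicDAG, validate
from .marginals import estimate_marginal
from .parameter_learning import _edge_pseudo_pairs, local_fit
from .copula_core import get_family

log = logging.getLogger(__name__)

__all__ = ["ScoreReport", "bic_score", "greedy_search",
           "learn_dynamic_structure", "EdgeScorer"]

#: maximum number of parents per child during search
MAX_IN_DEGREE = 3
#: default screening catalogue: one-parameter families covering the full
#: positive and negative τ range, for search speed; richer catalogues are
#: used for per-edge family selection once the structure is fixed
SCREEN_CATALOGUE = ("gaussian", "frank")


@dataclass(frozen=True)
class ScoreReport:
    loglik: float
    penalty: float
    bic: float
    K: int
    n_free_params: int


def _analysis_waves(panel, waves):
    return list(waves) if waves is not None else list(panel.waves)


class EdgeScorer:
    """Caches the maximized per-edge copula log-likelihood and its parameter
    count for every (x, y, lag) candidate, under a screening catalogue."""

    def __init__(self, panel, waves, part, seed=0, catalogue=SCREEN_CATALOGUE,
                 restarts=3, criterion="bic", penalty_weight=1.0):
        self.panel = panel
        self.waves = waves
        self.part = part
        self.seed = seed
        self.catalogue = catalogue
        self.restarts = restarts
        self._cache: dict = {}
        self.K = self._count_K()
        self.log_K = float(np.log(max(self.K, 2)))
        if criterion == "bic":
            base = 0.5 * self.log_K
        elif criterion == "aic":
            base = 1.0
        else:
            raise ValueError("criterion must be 'bic' or 'aic'")
        #: penalty charged per free copula parameter
        self.per_param_penalty = penalty_weight * base

    def _count_K(self) -> int:
        if self.part == "initial":
            return len(self.panel.wave_frame(self.waves[0]))
        total = 0
        for w0, w1 in zip(self.waves[:-1], self.waves[1:]):
            u0 = set(self.panel.wave_frame(w0)["unit"])
            u1 = set(self.panel.wave_frame(w1)["unit"])
            total += len(u0 & u1)
        return total

    def _edge_waves(self, lag):
        if self.part == "initial":
            return [self.waves[0]]
        # transition part: lag-0 edges live in slices 1..T-1, lag-1 edges
        # span consecutive pairs
        return self.waves[1:] if lag == 0 else self.waves

    def edge_contribution(self, x, y, lag):
        """(loglik, n_params) of the best screening-family fit for an edge."""
        key = (x, y, lag)
        if key in self._cache:
            return self._cache[key]
        for var in (x, y):
            for wv in self._edge_waves(lag):
                vals = self.panel.values(var, wv).dropna()
                if vals.nunique() < 2:
                    raise ValueError(
                        f"unfittable edge ({x}, {y}, lag={lag}): variable "
                        f"{var} is constant in wave {wv}")
        u, v = _edge_pseudo_pairs(self.panel, (x, y), self._edge_waves(lag),
                                  lag, self.seed)
        best = None
        for fam_name in self.catalogue:
            fam = get_family(fam_name)
            try:
                _, ll = local_fit(u, v, fam, restarts=self.restarts,
                                  seed=self.seed)
            except Exception as exc:
                log.debug("edge (%s,%s,lag=%s) family %s failed: %s",
                          x, y, lag, fam_name, exc)
                continue
            pen_ll = ll - self.per_param_penalty * fam.n_params
            if best is None or pen_ll > best[2]:
                best = (ll, fam.n_params, pen_ll)
        if best is None:
            raise RuntimeError(
                f"unfittable edge ({x}, {y}, lag={lag}): all screening "
                "families failed (constant variable?)")
        self._cache[key] = best
        return best

    def marginal_loglik(self, variables) -> float:
        """Graph-independent Σ log f_i(x_i) over nodes and scored waves."""
        total = 0.0
        waves = [self.waves[0]] if self.part == "initial" else self.waves[1:]
        for var in variables:
            vs = self.panel.schema[var]
            for wv in waves:
                vals = self.panel.values(var, wv).dropna().to_numpy()
                if len(vals) == 0:
                    continue
                scale = "ordinal" if vs.scale == "categorical" else vs.scale
                model = estimate_marginal(vals, scale)
                total += float(np.sum(model.logpmf(vals)))
        return total


def _edges_of(dag: DynamicDAG, part: str):
    if part == "initial":
        return [(x, y, 0) for x, y in dag.g0_edges]
    return list(dag.transition_edges)


def bic_score(panel, dag: DynamicDAG, part: str, waves=None, seed: int = 0,
              catalogue=SCREEN_CATALOGUE, restarts: int = 3,
              scorer: EdgeScorer | None = None, criterion: str = "bic",
              penalty_weight: float = 1.0) -> ScoreReport:
    """Graph score of one part of a dynamic graph (higher is better):
    BIC by default, or the AIC-penalty variant (one unit per parameter)."""
    if part not in ("initial", "transition"):
        raise ValueError("part must be 'initial' or 'transition'")
    validate(dag)
    waves = _analysis_waves(panel, waves)
    if scorer is None:
        scorer = EdgeScorer(panel, waves, part, seed=seed, catalogue=catalogue,
                            restarts=restarts, criterion=criterion,
                            penalty_weight=penalty_weight)
    ll = scorer.marginal_loglik(dag.variables)
    n_params = 0
    for x, y, lag in _edges_of(dag, part):
        ell, k, _ = scorer.edge_contribution(x, y, lag)
        ll += ell
        n_params += k
    penalty = scorer.per_param_penalty * n_params
    return ScoreReport(loglik=float(ll), penalty=float(penalty),
                       bic=float(ll - penalty), K=scorer.K,
                       n_free_params=n_params)


def _valid_state(edges, part, variables, exogenous):
    """Validity of an edge set: acyclic within slice, in-degree cap,
    exogenous nodes have no parents."""
    import networkx as nx

    indeg: dict = {}
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    for x, y, lag in edges:
        if y in exogenous:
            return False
        indeg[y] = indeg.get(y, 0) + 1
        if indeg[y] > MAX_IN_DEGREE:
            return False
        if lag == 0:
            if x == y:
                return False
            g.add_edge(x, y)
    return nx.is_directed_acyclic_graph(g)


def greedy_search(panel, constraints: DynamicDAG, part: str,
                  restarts: int = 5, seed: int = 0, waves=None,
                  catalogue=SCREEN_CATALOGUE, fit_restarts: int = 3,
                  criterion: str = "bic", penalty_weight: float = 1.0):
    """Hill-climb with add/delete/reverse moves inside the constraint
    template; returns (best DynamicDAG, ScoreReport).  Deterministic for a
    given seed; the first restart starts from the empty graph, later ones
    from random subgraphs of the template (edge inclusion probability 0.3).
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    validate(constraints)
    waves = _analysis_waves(panel, waves)
    scorer = EdgeScorer(panel, waves, part, seed=seed, catalogue=catalogue,
                        restarts=fit_restarts, criterion=criterion,
                        penalty_weight=penalty_weight)
    allowed = sorted(set(_edges_of(constraints, part)))
    variables = constraints.variables
    exog = set(constraints.exogenous)
    base_ll = scorer.marginal_loglik(variables)
    rng = np.random.default_rng(seed)

    def state_score(edges):
        s = base_ll
        for x, y, lag in edges:
            ell, k, _ = scorer.edge_contribution(x, y, lag)
            s += ell - scorer.per_param_penalty * k
        return s

    def climb(edges):
        edges = set(edges)
        score = state_score(edges)
        while True:
            best_move = None
            for e in allowed:
                if e in edges:
                    continue
                cand = edges | {e}
                if not _valid_state(cand, part, variables, exog):
                    continue
                s = state_score(cand)
                if best_move is None or s > best_move[0]:
                    best_move = (s, cand)
            for e in list(edges):
                cand = edges - {e}
                s = state_score(cand)
                if best_move is None or s > best_move[0]:
                    best_move = (s, cand)
                rev = (e[1], e[0], e[2])
                if rev in allowed and rev not in edges:
                    cand = (edges - {e}) | {rev}
                    if _valid_state(cand, part, variables, exog):
                        s = state_score(cand)
                        if best_move is None or s > best_move[0]:
                            best_move = (s, cand)
            if best_move is None or best_move[0] <= score + 1e-9:
                return edges, score
            score, edges = best_move
            log.debug("greedy move accepted: score=%.3f, |E|=%d", score,
                      len(edges))

    best_edges, best_score = None, -np.inf
    for r in range(restarts):
        if r == 0:
            start = set()
        else:
            start = {e for e in allowed if rng.uniform() < 0.3}
            while not _valid_state(start, part, variables, exog):
                start = {e for e in allowed if rng.uniform() < 0.3}
        edges, score = climb(start)
        if score > best_score:
            best_edges, best_score = edges, score

    if part == "initial":
        dag = DynamicDAG(variables, sorted((x, y) for x, y, _ in best_edges),
                         [], constraints.exogenous)
    else:
        dag = DynamicDAG(variables, [], sorted(best_edges),
                         constraints.exogenous)
    report = bic_score(panel, dag, part, waves=waves, scorer=scorer)
    return validate(dag), report


def learn_dynamic_structure(panel, constraints: DynamicDAG, restarts: int = 5,
                            seed: int = 0, waves=None,
                            catalogue=SCREEN_CATALOGUE, criterion: str = "bic",
                            penalty_weight: float = 1.0):
    """Learn G0 (on slice-0 records) and G→ (on stacked transitions)
    separately and merge; returns (DynamicDAG, {part: ScoreReport}).

    The total score is the sum of the two part scores (decomposability)."""
    waves = _analysis_waves(panel, waves)
    if len(waves) < 2:
        raise ValueError("need at least 2 waves to learn a transition graph")
    g0, rep0 = greedy_search(panel, constraints, "initial", restarts=restarts,
                             seed=seed, waves=waves, catalogue=catalogue,
                             criterion=criterion, penalty_weight=penalty_weight)
    gt, rept = greedy_search(panel, constraints, "transition",
                             restarts=restarts, seed=seed, waves=waves,
                             catalogue=catalogue, criterion=criterion,
                             penalty_weight=penalty_weight)
    merged = validate(DynamicDAG(constraints.variables, list(g0.g0_edges),
                                 list(gt.transition_edges),
                                 constraints.exogenous))
    total = rep0.bic + rept.bic
    return merged, {"initial": rep0, "transition": rept, "total_bic": total}
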