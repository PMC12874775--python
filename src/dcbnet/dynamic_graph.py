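"""Two-graph dynamic structure (G0, G->): validation, unrolling, accounting.

A dynamic Bayesian network over waves is defined by an initial graph G0 on
the slice-0 variables and a transition graph G-> over two consecutive
replications.  Cross-time edges run only from slice t-1 to slice t (lag 1);
within-slice edges (lag 0) must leave each slice acyclic.  Unrolling
replicates the structure over T slices; with the canonical 5 endogenous
processes over 3 analysis slices that yields 15 nodes and, for binary
states, 2^15 = 32,768 joint configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = ["DynamicDAG", "UnrolledDAG", "validate", "unroll",
           "count_configurations", "study_fixture", "edge_f1"]


@dataclass
class DynamicDAG:
    """Pair (G0, G->) over one set of process variables.

    ``g0_edges``: directed (x, y) pairs within slice 0.
    ``transition_edges``: directed (x, y, lag) triples; lag=1 means
    x at slice t-1 -> y at slice t, lag=0 means within slice t (t >= 1).
    ``exogenous``: variables (baselines, spillover proxies) that may have
    outgoing edges but never incoming ones.
    """

    variables: tuple[str, ...]
    g0_edges: list[tuple[str, str]] = field(default_factory=list)
    transition_edges: list[tuple[str, str, int]] = field(default_factory=list)
    exogenous: tuple[str, ...] = ()

    def within_slice_graph(self, part: str) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        if part == "initial":
            g.add_edges_from(self.g0_edges)
        else:
            g.add_edges_from((x, y) for x, y, lag in self.transition_edges
                             if lag == 0)
        return g


@dataclass
class UnrolledDAG:
    graph: nx.DiGraph
    n_slices: int

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return list(self.graph.edges)


def validate(dag: DynamicDAG) -> DynamicDAG:
    """Check time-slice constraints; return the graph or raise ValueError
    naming the offending edges."""
    vset = set(dag.variables)
    for x, y in dag.g0_edges:
        if x not in vset or y not in vset:
            raise ValueError(f"edge ({x}, {y}) references unknown variable")
        if x == y:
            raise ValueError(f"self-edge ({x}, {y}) within slice 0")
    for x, y, lag in dag.transition_edges:
        if x not in vset or y not in vset:
            raise ValueError(f"edge ({x}, {y}, lag={lag}) references unknown variable")
        if lag not in (0, 1):
            raise ValueError(
                f"edge ({x}, {y}, lag={lag}): cross-time edges may only run "
                "from slice t-1 to slice t (lag 0 or 1)"
            )
        if lag == 0 and x == y:
            raise ValueError(f"self-edge ({x}, {y}) within a slice")
    for x, y, *_ in list(dag.g0_edges) + list(dag.transition_edges):
        if y in dag.exogenous:
            raise ValueError(f"exogenous variable {y} cannot have parent {x}")
    for part in ("initial", "transition"):
        g = dag.within_slice_graph(part)
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            continue
        raise ValueError(
            f"within-slice cycle in {part} graph: "
            + " -> ".join(f"({a}, {b})" for a, b in cyc)
        )
    return dag


def unroll(dag: DynamicDAG, n_slices: int) -> UnrolledDAG:
    """Replicate the structure over ``n_slices``: slice 0 carries g0_edges,
    slices 1..T-1 carry transition_edges shifted to (t-1, t)."""
    validate(dag)
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    g = nx.DiGraph()
    for t in range(n_slices):
        g.add_nodes_from((v, t) for v in dag.variables)
    for x, y in dag.g0_edges:
        g.add_edge((x, 0), (y, 0))
    for t in range(1, n_slices):
        for x, y, lag in dag.transition_edges:
            g.add_edge((x, t - lag), (y, t))
    assert nx.is_directed_acyclic_graph(g)
    return UnrolledDAG(g, n_slices)


def count_configurations(unrolled: UnrolledDAG, states_per_node) -> int:
    """Joint configuration count: product of state counts over all nodes.

    ``states_per_node`` may be an int (shared) or a map keyed by variable
    name or by (variable, slice) node.
    """
    total = 1
    for node in unrolled.graph.nodes:
        if isinstance(states_per_node, int):
            k = states_per_node
        else:
            k = states_per_node.get(node, states_per_node.get(node[0]))
        if k is None or k < 1:
            raise ValueError(f"node {node} has no positive state count")
        total *= int(k)
    return total


#: within-slice structural edges of the canonical household-panel network
STUDY_G0_EDGES = [
    ("PS", "FS"), ("PS", "WQ"), ("PS", "MSW"),
    ("WQ", "FS"), ("FS", "CUS"), ("WQ", "CUS"), ("MSW", "CUS"),
]
#: autoregressive persistence self-loops (slice t-1 -> t)
STUDY_SELF_LOOPS = ["CUS", "FS", "WQ"]


def study_fixture(with_cpi: bool = True, baseline_parents: tuple[str, ...] = ()) -> DynamicDAG:
    """Canonical fixture graph: program participation (PS) driving food
    security (FS), wealth (WQ) and mother wellbeing (MSW) within each slice,
    all three feeding child undernutrition status (CUS); persistence
    self-loops for CUS/FS/WQ across slices; optionally a leave-one-out
    community program intensity (CPI) spillover node with candidate edges to
    every endogenous variable, and exogenous baseline parents of slice 0."""
    variables = ["PS", "FS", "WQ", "MSW", "CUS"]
    exog = []
    g0 = list(STUDY_G0_EDGES)
    trans = [(v, v, 1) for v in STUDY_SELF_LOOPS]
    trans += [(x, y, 0) for x, y in STUDY_G0_EDGES]
    if with_cpi:
        variables.append("CPI")
        exog.append("CPI")
        for tgt in ["PS", "FS", "WQ", "MSW", "CUS"]:
            g0.append(("CPI", tgt))
            trans.append(("CPI", tgt, 0))
    for b in baseline_parents:
        variables.append(b)
        exog.append(b)
        for tgt in ["FS", "WQ", "CUS"]:
            g0.append((b, tgt))
    return validate(DynamicDAG(tuple(variables), g0, trans, tuple(exog)))


def edge_f1(learned: DynamicDAG, truth: DynamicDAG) -> float:
    """F1 of the learned edge set against a reference structure."""
    def canon(dag):
        return set(map(tuple, dag.g0_edges)) | {
            (x, y, lag) for x, y, lag in dag.transition_edges
        }
    L, T = canon(learned), canon(truth)
    tp = len(L & T)
    if tp == 0:
        return 0.0
    prec = tp / len(L)
    rec = tp / len(T)
    return 2 * prec * rec / (prec + rec)


# -- serialization ---------------------------------------------------------

def to_json(dag: DynamicDAG) -> str:
    """Edge-list JSON ({from, to, lag}) with variable/exogenous declarations."""
    return json.dumps(
        {
            "variables": list(dag.variables),
            "exogenous": list(dag.exogenous),
            "edges": (
                [{"from": x, "to": y, "lag": "g0"} for x, y in dag.g0_edges]
                + [{"from": x, "to": y, "lag": lag} for x, y, lag in dag.transition_edges]
            ),
        },
        indent=2,
    )


def from_json(text: str) -> DynamicDAG:
    d = json.loads(text)
    g0 = [(e["from"], e["to"]) for e in d["edges"] if e["lag"] == "g0"]
    trans = [(e["from"], e["to"], int(e["lag"])) for e in d["edges"] if e["lag"] != "g0"]
    return validate(
        DynamicDAG(tuple(d["variables"]), g0, trans, tuple(d.get("exogenous", ())))
    )


def to_dot(dag: DynamicDAG, n_slices: int = 3) -> str:
    """Rendering-friendly DOT text of the unrolled graph."""
    unrolled = unroll(dag, n_slices)
    lines = ["digraph dcbn {", "  rankdir=LR;"]
    for (v, t) in unrolled.graph.nodes:
        lines.append(f'  "{v}_{t}" [label="{v} (t={t})"];')
    for (a, ta), (b, tb) in unrolled.graph.edges:
        lines.append(f'  "{a}_{ta}" -> "{b}_{tb}";')
    lines.append("}")
    return "\n".join(lines)
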