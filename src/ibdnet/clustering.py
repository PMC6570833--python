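"""Graph clustering: Markov Cluster Algorithm and edge-betweenness communities.

MCL simulates flow on the graph: the column-stochastic transition matrix
(adjacency plus unit self-loops) is alternately expanded (matrix power,
spreading flow) and inflated (entrywise power + column renormalization,
sharpening it) until a fixpoint; clusters are read off the attractor rows.
Inflation controls granularity -- the default of 3 is deliberately fine.

The edge-betweenness method is the Girvan-Newman divisive scheme: the
edge carrying the most shortest paths is removed repeatedly and the
partition (along the removal sequence) with maximal Newman-Girvan
modularity of the original graph is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ClusterAssignment",
    "MclParams",
    "MclConvergenceError",
    "mcl",
    "edge_betweenness_communities",
]


class MclConvergenceError(RuntimeError):
    """MCL failed to reach a fixpoint within the iteration budget."""


@dataclass(frozen=True)
class ClusterAssignment:
    """node -> 1-based contiguous cluster id."""

    assignment: dict[str, int]
    n_clusters: int

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if ids and ids != set(range(1, self.n_clusters + 1)):
            raise ValueError("cluster ids must be contiguous from 1")

    def clusters(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_clusters)]
        for node, cid in self.assignment.items():
            out[cid - 1].add(node)
        return out

    def labels(self, order: list[str]) -> list[int]:
        return [self.assignment[n] for n in order]


@dataclass(frozen=True)
class MclParams:
    inflation: float = 3.0
    expansion: int = 2
    pruning: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


def _partition_from_sets(nodes: list[str], groups: list[set[str]]) -> ClusterAssignment:
    """Number groups 1..k by their smallest member (deterministic)."""
    groups = sorted((g for g in groups if g), key=lambda g: min(g))
    assignment = {}
    for cid, grp in enumerate(groups, start=1):
        for n in grp:
            assignment[n] = cid
    for n in nodes:  # safety: any stray node becomes its own cluster
        if n not in assignment:
            groups.append({n})
            assignment[n] = len(groups)
    return ClusterAssignment(assignment=assignment, n_clusters=len(groups))


def mcl(g: nx.Graph, params: MclParams = MclParams()) -> ClusterAssignment:
    """Markov clustering of an undirected (optionally weighted) graph.

    Edge weights (``confidence``) are used as flow capacities when present;
    unit self-loops are added to damp parity oscillation. Overlapping
    attractor systems are merged so every node lands in exactly one cluster.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = float(d.get("confidence", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    np.fill_diagonal(m, 1.0)  # self-loops
    m /= m.sum(axis=0, keepdims=True)

    for _ in range(params.max_iter):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.pruning] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        residual = float(np.abs(m - prev).max())
        if residual < params.tol:
            break
    else:
        raise MclConvergenceError(
            f"MCL did not converge in {params.max_iter} iterations "
            f"(residual {residual:.3g})"
        )

    # attractors: rows with mass on the diagonal; cluster = row support
    thr = max(params.pruning, 1e-9)
    groups: list[set[str]] = []
    for i in range(n):
        if m[i, i] > thr:
            support = {nodes[j] for j in np.nonzero(m[i] > thr)[0]}
            groups.append(support)
    # merge overlapping attractor systems
    merged: list[set[str]] = []
    for grp in groups:
        hit = [s for s in merged if s & grp]
        for s in hit:
            merged.remove(s)
            grp |= s
        merged.append(grp)
    return _partition_from_sets(nodes, merged)


def edge_betweenness_communities(g: nx.Graph) -> ClusterAssignment:
    """Girvan-Newman divisive clustering, best-modularity cut returned.

    At each step the edge with maximal edge betweenness is removed (ties
    by lexicographic endpoint pair); of the component partitions observed
    along the way, the one maximizing modularity of the *original* graph
    wins. Components never merge, so clusters cannot span disconnected
    parts of the input.
    """
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        return _partition_from_sets(nodes, [{n} for n in nodes])

    work = g.copy()
    best_groups = [set(c) for c in nx.connected_components(work)]
    best_q = nx.community.modularity(g, best_groups)
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, normalized=False)
        top = max(eb.values())
        candidates = [tuple(sorted(e)) for e, v in eb.items() if v >= top - 1e-12]
        work.remove_edge(*min(candidates))
        groups = [set(c) for c in nx.connected_components(work)]
        q = nx.community.modularity(g, groups)
        if q > best_q + 1e-12:
            best_q = q
            best_groups = groups
    return _partition_from_sets(nodes, best_groups)
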