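"""Node centralities and the weighted combined importance score.

Three views of topological importance are combined: hubs (degree
centrality), reachability (Latora harmonic closeness, which handles
disconnected graphs natively), and bottlenecks (betweenness). Each raw
centrality is min-max rescaled across the network's nodes and the
combined score is the weighted sum 0.2*degree + 0.3*closeness +
0.5*betweenness by default, the weighting reflecting the relative
biological importance usually attributed to these metrics in protein
networks. Centralities are computed on the unweighted topology; a
confidence-weighted distance mode (d = 1 - confidence) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .netbuild import CONFIDENCE

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreWeights",
    "CentralityRecord",
    "degree_centrality",
    "harmonic_closeness",
    "betweenness",
    "combined_score",
    "centrality_records",
    "rank_nodes",
]


@dataclass(frozen=True)
class ScoreWeights:
    w_deg: float = 0.2
    w_clo: float = 0.3
    w_bet: float = 0.5

    def __post_init__(self) -> None:
        if min(self.w_deg, self.w_clo, self.w_bet) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_deg + self.w_clo + self.w_bet - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    c_deg: float
    c_clo: float
    c_bet: float
    combined: float


def _weight_key(weighted: bool):
    return "distance" if weighted else None


def _with_distance(g: nx.Graph) -> nx.Graph:
    h = g.copy()
    for _u, _v, d in h.edges(data=True):
        d["distance"] = 1.0 - d.get(CONFIDENCE, 0.0)
    return h


def degree_centrality(g: nx.Graph) -> dict[str, float]:
    """deg(v)/(n-1); all zeros (with a warning) on a single-node graph."""
    if g.number_of_nodes() < 2:
        logger.warning("degree centrality undefined on <2 nodes; returning zeros")
        return {n: 0.0 for n in g.nodes}
    return nx.degree_centrality(g)


def harmonic_closeness(
    g: nx.Graph, normalized: bool = True, weighted: bool = False
) -> dict[str, float]:
    """Latora harmonic closeness: mean reciprocal shortest-path distance.

    C(v) = (1/(n-1)) * sum_u 1/d(u,v), with 1/inf = 0 for unreachable
    pairs; ``normalized=False`` returns the raw reciprocal-distance sum.
    """
    n = g.number_of_nodes()
    h = _with_distance(g) if weighted else g
    raw = nx.harmonic_centrality(h, distance=_weight_key(weighted))
    if not normalized or n < 2:
        return {k: float(v) for k, v in raw.items()}
    return {k: v / (n - 1) for k, v in raw.items()}


def betweenness(g: nx.Graph, weighted: bool = False) -> dict[str, float]:
    """Betweenness centrality normalized by (n-1)(n-2)/2 (undirected)."""
    h = _with_distance(g) if weighted else g
    return nx.betweenness_centrality(h, normalized=True, weight=_weight_key(weighted))


def _minmax(values: dict[str, float]) -> dict[str, float]:
    lo, hi = min(values.values()), max(values.values())
    if hi - lo <= 0:
        return {k: 0.0 for k in values}  # constant column carries no signal
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def combined_score(
    g: nx.Graph,
    weights: ScoreWeights = ScoreWeights(),
    normalize: bool = True,
    weighted_paths: bool = False,
) -> dict[str, float]:
    """Weighted combination of the three centralities per node.

    With ``normalize=True`` (default) each centrality is min-max rescaled
    to [0, 1] across nodes before weighting so the weights act on
    comparable scales; ``normalize=False`` combines the raw values.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    cd = degree_centrality(g)
    cc = harmonic_closeness(g, weighted=weighted_paths)
    cb = betweenness(g, weighted=weighted_paths)
    if normalize:
        cd, cc, cb = _minmax(cd), _minmax(cc), _minmax(cb)
    return {
        n: weights.w_deg * cd[n] + weights.w_clo * cc[n] + weights.w_bet * cb[n]
        for n in g.nodes
    }


def centrality_records(
    g: nx.Graph, weights: ScoreWeights = ScoreWeights(), normalize: bool = True
) -> list[CentralityRecord]:
    """Raw centralities plus combined score per node, in rank order."""
    cd = degree_centrality(g)
    cc = harmonic_closeness(g)
    cb = betweenness(g)
    comb = combined_score(g, weights=weights, normalize=normalize)
    order = rank_nodes(comb)
    return [
        CentralityRecord(node=n, c_deg=cd[n], c_clo=cc[n], c_bet=cb[n], combined=comb[n])
        for n in order
    ]


def rank_nodes(scores: dict[str, float]) -> list[str]:
    """Nodes sorted by combined score descending, ties by symbol ascending."""
    return sorted(scores, key=lambda n: (-scores[n], n))
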