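"""Gene-set over-representation and complementary pathway networks.

Over-representation is the hypergeometric (one-sided) test of the overlap
between a query gene list and each database set against a background of
genes; the top-ranked sets act as "seed" pathways. The complementary
network then connects those seeds through an offline pathway-pathway
scaffold (edges = gene-overlap Jaccard above a floor), greedily adding the
fewest intermediate pathways needed to pull the seed subgraph into one
connected component; added pathways are the "complementary" ones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetDB

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "enrich",
    "pathway_graph",
    "complementary_network",
]

ROLE = "role"  # pathway-node attribute: seed / complementary
JACCARD = "weight"  # edge attribute on pathway graphs


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int  # overlap
    K: int  # set size (within background)
    n: int  # query size (within background)
    N: int  # background size
    p: float
    p_adj: float
    rank: int


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for hypergeometric X ~ (N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes: list[str],
    db: GeneSetDB,
    background: set[str] | None = None,
    top: int = 10,
) -> list[EnrichmentResult]:
    """Rank database sets by over-representation of the query; return top hits.

    Background defaults to the union of all database genes. Sets with no
    overlap are excluded. Ranking is by p ascending, ties by larger
    overlap then set id; BH adjustment is computed over all tested sets
    but does not gate selection (a fixed number of seeds is taken).
    """
    bg = set(background) if background is not None else db.all_genes()
    query = set(query_genes) & bg
    if not query:
        raise ValueError("query has no genes in the background")
    n, N = len(query), len(bg)
    tested: list[tuple[str, int, int, float]] = []
    for sid in db.ids():
        members = set(db.members(sid)) & bg
        k = len(query & members)
        if k == 0:
            continue
        tested.append((sid, k, len(members), hypergeom_tail(k, len(members), n, N)))
    if not tested:
        return []
    p_adj = multipletests([t[3] for t in tested], method="fdr_bh")[1]
    order = sorted(
        range(len(tested)), key=lambda i: (tested[i][3], -tested[i][1], tested[i][0])
    )
    results = []
    for rank, i in enumerate(order[:top], start=1):
        sid, k, K, p = tested[i]
        results.append(
            EnrichmentResult(set_id=sid, k=k, K=K, n=n, N=N, p=p, p_adj=float(p_adj[i]), rank=rank)
        )
    return results


def pathway_graph(db: GeneSetDB, min_jaccard: float = 0.05) -> nx.Graph:
    """Pathway-pathway scaffold: nodes are all sets, edges Jaccard >= floor."""
    g = nx.Graph()
    ids = db.ids()
    members = {sid: set(db.members(sid)) for sid in ids}
    g.add_nodes_from(ids)
    for a, b in itertools.combinations(ids, 2):
        inter = len(members[a] & members[b])
        if inter == 0:
            continue
        j = inter / len(members[a] | members[b])
        if j >= min_jaccard:
            g.add_edge(a, b, **{JACCARD: j})
    return g


def _components(scaffold: nx.Graph, included: set[str]) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(scaffold.subgraph(included))]


def _best_connecting_path(
    scaffold: nx.Graph, comps: list[set[str]]
) -> list[str] | None:
    """Shortest scaffold path joining two different components.

    Fewest intermediates first; ties by summed edge weight descending,
    then by the lexicographically smallest node sequence.
    """
    best = None
    best_key = None
    for i, j in itertools.combinations(range(len(comps)), 2):
        for u in sorted(comps[i]):
            for v in sorted(comps[j]):
                try:
                    length = nx.shortest_path_length(scaffold, u, v)
                except nx.NetworkXNoPath:
                    continue
                for path in nx.all_shortest_paths(scaffold, u, v):
                    weight = sum(
                        scaffold[a][b][JACCARD] for a, b in zip(path, path[1:])
                    )
                    key = (length - 1, -weight, tuple(path))
                    if best_key is None or key < best_key:
                        best_key = key
                        best = path
    return best


def complementary_network(seeds: list[str], scaffold: nx.Graph) -> nx.Graph:
    """Connect seed pathways through the scaffold, adding intermediates.

    Returns the scaffold subgraph induced on seeds plus the added
    complementary pathways, node roles marked. A final pruning pass drops
    any complementary pathway whose removal does not disconnect the
    network, so every added pathway is structurally necessary. If some
    seeds live in scaffold components with no connecting path, the
    remaining components are returned as-is with a warning.
    """
    seeds = list(dict.fromkeys(seeds))
    missing = [s for s in seeds if s not in scaffold]
    if missing:
        raise ValueError(f"seeds absent from scaffold: {missing}")
    included = set(seeds)
    while True:
        comps = _components(scaffold, included)
        if len(comps) <= 1:
            break
        path = _best_connecting_path(scaffold, comps)
        if path is None:
            logger.warning(
                "%d seed components cannot be connected in the scaffold", len(comps)
            )
            break
        intermediates = [p for p in path[1:-1] if p not in included]
        if not intermediates:  # the two endpoints were already adjacent
            # adjacency inside `included` is captured by the induced subgraph,
            # so an empty intermediate list means no progress is possible
            logger.warning("no progress connecting pathway components; stopping")
            break
        included.update(intermediates)

    complementary = included - set(seeds)
    # prune additions that turned out redundant once later paths landed
    changed = True
    while changed:
        changed = False
        base = len(_components(scaffold, included))
        for node in sorted(complementary):
            trial = included - {node}
            if len(_components(scaffold, trial)) <= base:
                included = trial
                complementary.discard(node)
                changed = True
                break

    out = nx.Graph()
    for n in sorted(included):
        out.add_node(n, **{ROLE: "seed" if n in set(seeds) else "complementary"})
    for u, v, d in scaffold.subgraph(included).edges(data=True):
        out.add_edge(u, v, **{JACCARD: d[JACCARD]})
    return out
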