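"""Protein-association network construction with capped shell expansion.

Given a list of risk genes, map them to canonical protein symbols, then
grow a confidence-thresholded association network around them: up to 20
first-shell interactors (direct neighbors of the seeds) and 10 second-shell
interactors (neighbors of the first shell), candidates ranked by summed
edge confidence to the network built so far. All qualifying edges among
included nodes are materialized and isolated nodes are hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .io import InteractionTable

logger = logging.getLogger(__name__)

__all__ = ["ShellCaps", "map_genes_to_proteins", "expand_seed_network", "graph_from_table"]

ROLE = "role"  # node attribute: seed / shell1 / shell2
CONFIDENCE = "confidence"  # edge attribute


@dataclass(frozen=True)
class ShellCaps:
    """Interactor caps: at most 20 first-shell + 10 second-shell additions."""

    max_shell1: int = 20
    max_shell2: int = 10

    def __post_init__(self) -> None:
        if self.max_shell1 < 0 or self.max_shell2 < 0:
            raise ValueError("shell caps must be non-negative")

    @property
    def max_total(self) -> int:
        return self.max_shell1 + self.max_shell2


def map_genes_to_proteins(
    genes: Iterable[str], alias_table: Mapping[str, str] | None = None
) -> tuple[list[str], list[str]]:
    """Resolve gene symbols to canonical protein symbols via an alias table.

    Genes absent from the alias table map to themselves (identity); the
    second return value lists such unmapped symbols so they are reported,
    not silently dropped. Raises if the resolved set is empty.
    """
    alias_table = alias_table or {}
    seen: set[str] = set()
    resolved: list[str] = []
    unmapped: list[str] = []
    for g in genes:
        if g in alias_table:
            target = alias_table[g]
        else:
            target = g
            unmapped.append(g)
        if target not in seen:
            seen.add(target)
            resolved.append(target)
    if not resolved:
        raise ValueError("gene list resolved to an empty protein set")
    if unmapped:
        logger.info("%d gene symbols had no alias entry (kept as-is)", len(unmapped))
    return resolved, unmapped


def graph_from_table(interactions: InteractionTable, min_score: float = 0.0) -> nx.Graph:
    """Undirected confidence-weighted graph from an interaction table."""
    g = nx.Graph()
    for a, b, s in interactions.pairs():
        if s >= min_score:
            g.add_edge(a, b, **{CONFIDENCE: s})
    return g


def _attachment_rank(g: nx.Graph, candidates: set[str], anchor: set[str]) -> list[str]:
    """Candidates ordered by summed confidence of edges into `anchor`, desc;
    ties broken by symbol ascending."""
    strength = {}
    for c in candidates:
        s = sum(
            d[CONFIDENCE] for _u, v, d in g.edges(c, data=True) if v in anchor
        )
        strength[c] = s
    return sorted(candidates, key=lambda c: (-strength[c], c))


def expand_seed_network(
    interactions: InteractionTable,
    seeds: Iterable[str],
    caps: ShellCaps = ShellCaps(),
    min_score: float = 0.400,
) -> nx.Graph:
    """Build the seed network and enrich it with capped shell interactors.

    Returns a graph whose nodes carry a ``role`` attribute (seed / shell1 /
    shell2) and whose edges carry the combined ``confidence``. Nodes left
    without any qualifying edge are removed from the result (hidden), but
    the returned graph's ``graph['hidden_seeds']`` lists hidden seed
    symbols for reporting.
    """
    seeds = list(dict.fromkeys(seeds))
    full = graph_from_table(interactions, min_score=min_score)
    present = [s for s in seeds if s in full]
    if not present:
        raise ValueError(f"no seed present in the interaction table: missing {seeds}")

    seed_set = set(present)
    shell1_pool = {n for s in present for n in full.neighbors(s)} - seed_set
    shell1 = _attachment_rank(full, shell1_pool, seed_set)[: caps.max_shell1]

    current = seed_set | set(shell1)
    shell2_pool = {n for s in shell1 for n in full.neighbors(s)} - current
    shell2 = _attachment_rank(full, shell2_pool, current)[: caps.max_shell2]

    included = current | set(shell2)
    net = nx.Graph()
    roles = (
        {s: "seed" for s in seed_set}
        | {s: "shell1" for s in shell1}
        | {s: "shell2" for s in shell2}
    )
    for n in sorted(included):
        net.add_node(n, **{ROLE: roles[n]})
    for u, v, d in full.subgraph(included).edges(data=True):
        net.add_edge(u, v, **{CONFIDENCE: d[CONFIDENCE]})

    isolated = [n for n in net.nodes if net.degree(n) == 0]
    hidden_seeds = sorted(n for n in isolated if roles[n] == "seed")
    hidden_seeds += sorted(s for s in seeds if s not in full)
    net.remove_nodes_from(isolated)
    net.graph["hidden_seeds"] = hidden_seeds
    net.graph["min_score"] = min_score
    return net
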