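"""Pathway ranking, phenotype set comparison and the disease-disease network.

A pathway's rank score is the mean combined centrality score of its member
proteins that are present in the analyzed network ("contributing"
proteins); pathways with no contributing protein are omitted. Phenotype
SNP/pathway lists are compared as exact Venn regions (up to four lists),
two method outputs are merged into common/exclusive partitions, and
diseases are linked into a network weighted by the Jaccard overlap of
their pathway profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .io import GeneSetDB

__all__ = [
    "PathwayScore",
    "pathway_rank",
    "venn_regions",
    "merge_methods",
    "disease_network",
]


@dataclass(frozen=True)
class PathwayScore:
    set_id: str
    contributing: tuple[str, ...]
    mean_combined: float
    rank: int


def pathway_rank(
    db: GeneSetDB,
    scores: Mapping[str, float],
    network_nodes: Iterable[str],
) -> list[PathwayScore]:
    """Rank gene sets by mean combined score of their in-network members."""
    nodes = set(network_nodes)
    scored: list[tuple[str, tuple[str, ...], float]] = []
    for sid in db.ids():
        present = tuple(sorted(set(db.members(sid)) & nodes))
        if not present:
            continue
        mean = sum(scores[p] for p in present) / len(present)
        scored.append((sid, present, mean))
    scored.sort(key=lambda t: (-t[2], t[0]))
    return [
        PathwayScore(set_id=sid, contributing=present, mean_combined=mean, rank=r)
        for r, (sid, present, mean) in enumerate(scored, start=1)
    ]


def venn_regions(named_lists: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], set[str]]:
    """Exact Venn decomposition of 2-4 named lists.

    Keys are tuples of the list names an item belongs to (in input order);
    all 2^k - 1 membership regions are present, possibly empty. Regions
    are pairwise disjoint and their union is the union of the inputs.
    """
    names = list(named_lists)
    if not 2 <= len(names) <= 4:
        raise ValueError(f"venn comparison needs 2-4 lists, got {len(names)}")
    sets = {name: set(named_lists[name]) for name in names}
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[combo] = inside - outside
    total = set.union(*sets.values())
    assert sum(len(v) for v in regions.values()) == len(total)
    return regions


def merge_methods(
    pathways_m1: Iterable[str], pathways_m2: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition two methods' pathway lists into (common, only_m1, only_m2)."""
    s1, s2 = set(pathways_m1), set(pathways_m2)
    return s1 & s2, s1 - s2, s2 - s1


def disease_network(
    profiles: Mapping[str, Iterable[str]], min_shared: int = 1
) -> nx.Graph:
    """Disease-disease graph from shared pathway profiles.

    Edge between two diseases iff they share at least ``min_shared``
    pathways; edge weight is the Jaccard index of their profiles. Diseases
    with no edge are retained with ``isolated=True``.
    """
    diseases = list(profiles)
    if len(diseases) < 2:
        raise ValueError("need at least 2 disease profiles")
    sets = {d: set(profiles[d]) for d in diseases}
    for d, s in sets.items():
        if not s:
            raise ValueError(f"disease {d!r} has an empty pathway profile")
    g = nx.Graph()
    g.add_nodes_from(diseases)
    for a, b in itertools.combinations(diseases, 2):
        shared = sets[a] & sets[b]
        if len(shared) >= min_shared and shared:
            g.add_edge(a, b, weight=len(shared) / len(sets[a] | sets[b]), shared=len(shared))
    for d in diseases:
        g.nodes[d]["isolated"] = g.degree(d) == 0
    return g
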