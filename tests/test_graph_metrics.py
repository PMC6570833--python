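"""Centralities against exhaustive brute-force oracles and closed forms.

The oracle computes all-pairs shortest paths by BFS and enumerates every
geodesic explicitly (DFS over minimal-length paths), independent of the
library routines being checked.
"""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from ibdnet.graph_metrics import (
    ScoreWeights,
    betweenness,
    combined_score,
    degree_centrality,
    harmonic_closeness,
    rank_nodes,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def bfs_distances(g, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_degree(g):
    n = g.number_of_nodes()
    return {v: g.degree(v) / (n - 1) for v in g}


def brute_harmonic(g):
    n = g.number_of_nodes()
    out = {}
    for v in g:
        dist = bfs_distances(g, v)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v) / (n - 1)
    return out


def enumerate_geodesics(g, s, t):
    """All shortest s-t paths via DFS constrained to decreasing distance-to-t."""
    dist_t = bfs_distances(g, t)
    if s not in dist_t:
        return []
    paths = []

    def walk(u, acc):
        if u == t:
            paths.append(list(acc))
            return
        for v in g.neighbors(u):
            if v in dist_t and dist_t[v] == dist_t[u] - 1:
                acc.append(v)
                walk(v, acc)
                acc.pop()

    walk(s, [s])
    return paths


def brute_betweenness(g):
    n = g.number_of_nodes()
    out = {v: 0.0 for v in g}
    for s, t in itertools.combinations(g.nodes, 2):
        geos = enumerate_geodesics(g, s, t)
        if not geos:
            continue
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in geos if v in p)
            out[v] += through / len(geos)
    norm = (n - 1) * (n - 2) / 2
    return {v: (x / norm if norm else 0.0) for v, x in out.items()}


def random_small_graphs(n_graphs, rng):
    for _ in range(n_graphs):
        n = int(rng.integers(2, 8))
        p = float(rng.uniform(0.15, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        yield nx.relabel_nodes(g, {i: f"n{i}" for i in g})


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _named(g):
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g})


class TestClosedForms:
    def test_complete_graph_degree_one(self):
        g = _named(nx.complete_graph(4))
        assert all(v == pytest.approx(1.0) for v in degree_centrality(g).values())

    def test_star_degree(self):
        g = _named(nx.star_graph(4))
        d = degree_centrality(g)
        assert d["n0"] == pytest.approx(1.0)
        assert d["n1"] == pytest.approx(0.25)

    def test_path3_harmonic(self):
        g = _named(nx.path_graph(3))
        c = harmonic_closeness(g)
        assert c["n1"] == pytest.approx(1.0)
        assert c["n0"] == pytest.approx(0.75)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        c = harmonic_closeness(g)
        assert all(v == pytest.approx(1 / 3) for v in c.values())

    def test_path3_betweenness(self):
        g = _named(nx.path_graph(3))
        b = betweenness(g)
        assert b["n1"] == pytest.approx(1.0)
        assert b["n0"] == pytest.approx(0.0)

    def test_cycle4_betweenness(self):
        g = _named(nx.cycle_graph(4))
        b = betweenness(g)
        assert all(v == pytest.approx(1 / 6) for v in b.values())
        assert brute_betweenness(g)["n0"] == pytest.approx(1 / 6)

    def test_single_node_degree_zero_with_warning(self, caplog):
        g = nx.Graph()
        g.add_node("x")
        with caplog.at_level("WARNING"):
            assert degree_centrality(g) == {"x": 0.0}
        assert "undefined" in caplog.text


class TestBruteForceEquivalence:
    def test_all_three_centralities_on_random_small_graphs(self):
        rng = np.random.default_rng(2024)
        for g in random_small_graphs(120, rng):
            assert degree_centrality(g) == pytest.approx(brute_degree(g))
            assert harmonic_closeness(g) == pytest.approx(brute_harmonic(g))
            assert betweenness(g) == pytest.approx(brute_betweenness(g), abs=1e-12)


class TestCombinedScore:
    def test_star_extremes(self):
        g = _named(nx.star_graph(4))
        cs = combined_score(g)
        assert cs["n0"] == pytest.approx(1.0)  # max in all three centralities
        assert cs["n1"] == pytest.approx(0.0)  # min in all three

    def test_relabel_invariance(self):
        g = _named(nx.gnp_random_graph(7, 0.5, seed=5))
        cs = combined_score(g)
        relabel = {n: f"x_{n}" for n in g}
        cs2 = combined_score(nx.relabel_nodes(g, relabel))
        for n, v in cs.items():
            assert cs2[relabel[n]] == pytest.approx(v)

    def test_pure_betweenness_weights_reproduce_betweenness_ranking(self):
        g = _named(nx.gnp_random_graph(10, 0.35, seed=11))
        cs = combined_score(g, ScoreWeights(0.0, 0.0, 1.0))
        assert rank_nodes(cs) == rank_nodes(betweenness(g))

    def test_weight_shift_moves_bottleneck_up(self):
        # barbell: bridge node has top betweenness but low degree
        g = _named(nx.barbell_graph(5, 1))
        bridge = max(betweenness(g), key=betweenness(g).get)
        heavy_bet = combined_score(g, ScoreWeights(0.1, 0.1, 0.8))
        heavy_deg = combined_score(g, ScoreWeights(0.8, 0.1, 0.1))
        rank_bet = rank_nodes(heavy_bet).index(bridge)
        rank_deg = rank_nodes(heavy_deg).index(bridge)
        assert rank_bet < rank_deg

    def test_constant_column_maps_to_zero(self):
        g = _named(nx.cycle_graph(5))  # all centralities constant
        assert all(v == 0.0 for v in combined_score(g).values())


class TestRanking:
    def test_descending_order(self):
        assert rank_nodes({"A": 0.9, "B": 0.1}) == ["A", "B"]

    def test_tie_broken_by_symbol(self):
        assert rank_nodes({"B": 0.5, "A": 0.5}) == ["A", "B"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        scores = {f"n{i}": float(rng.random()) for i in range(20)}
        expected = [k for k, _v in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert rank_nodes(scores) == expected
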