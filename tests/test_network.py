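import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from resistnet.activity import ActivityResult
from resistnet.diffexp import ContrastResult
from resistnet.network import (
    SeedSet,
    cluster_activity,
    geodesic_subgraph,
    louvain_cluster,
    match_clusters,
    node_importance,
    rewire_null,
    select_seeds,
    subgraph_enrichment,
)


def _seedset(directions):
    table = pd.DataFrame(
        {
            "direction": list(directions.values()),
            "log2fc": [1.0 if d == "up" else -1.0 for d in directions.values()],
            "expr_q": 0.01,
            "nes": [6.0 if d == "up" else -6.0 for d in directions.values()],
            "act_q": 0.01,
        },
        index=list(directions),
    )
    return SeedSet(table)


def _expr(rows):
    table = pd.DataFrame(rows, columns=["log2fc", "qval"]).assign(se=1.0, stat=0.0, pval=0.01)
    table.index = [f"p{i}" for i in range(len(rows))]
    return ContrastResult(("A", "B"), table)


def _act(rows):
    table = pd.DataFrame(rows, columns=["nes", "qval"]).assign(
        es=0.0, pval=0.01, n_targets=10
    )
    table["significant"] = (table["qval"] < 0.10) & (table["nes"].abs() > 5)
    table.index = [f"p{i}" for i in range(len(rows))]
    return ActivityResult(table)


class TestSelectSeeds:
    def test_exactly_matching_rows_selected(self):
        # 6 proteins; only p0 (up) and p3 (down) satisfy all four criteria
        expr = _expr(
            [(2.0, 0.01), (2.0, 0.5), (1.0, 0.05), (-1.5, 0.02), (-1.0, 0.01), (0.5, 0.01)]
        )
        act = _act(
            [(7.0, 0.01), (8.0, 0.01), (3.0, 0.01), (-6.0, 0.05), (6.0, 0.01), (5.5, 0.5)]
        )
        seeds = select_seeds(expr, act)
        assert set(seeds.proteins) == {"p0", "p3"}
        assert seeds.direction("p0") == "up"
        assert seeds.direction("p3") == "down"

    def test_opposite_signs_excluded(self):
        expr = _expr([(2.0, 0.01)])
        act = _act([(-7.0, 0.01)])
        assert len(select_seeds(expr, act)) == 0


class TestGeodesicSubgraph:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        sub = geodesic_subgraph(g, _seedset({"A": "up", "C": "down"}))
        assert set(sub.graph.nodes) == {"A", "B", "C"}
        assert sub.graph.number_of_edges() == 2

    def test_cycle_includes_all_tied_geodesics(self):
        g = nx.cycle_graph(["A", "B", "C", "D"])
        sub = geodesic_subgraph(g, _seedset({"A": "up", "C": "down"}))
        assert set(sub.graph.nodes) == {"A", "B", "C", "D"}
        assert sub.graph.number_of_edges() == 4

    @staticmethod
    def _brute_force(graph, seeds):
        """Oracle: enumerate all simple paths of geodesic length per pair."""
        nodes, edges = set(), set()
        for s, t in itertools.combinations(seeds, 2):
            try:
                d = nx.shortest_path_length(graph, s, t)
            except nx.NetworkXNoPath:
                continue
            for path in nx.all_simple_paths(graph, s, t, cutoff=d):
                if len(path) - 1 == d:
                    nodes.update(path)
                    edges.update(frozenset(e) for e in zip(path, path[1:]))
        return nodes, edges

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            g = nx.gnp_random_graph(30, 0.12, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            seeds = list(rng.choice(sorted(g.nodes), 4, replace=False))
            sub = geodesic_subgraph(g, _seedset({s: "up" for s in seeds}))
            nodes, edges = self._brute_force(g, seeds)
            assert set(sub.graph.nodes) == nodes
            assert {frozenset(e) for e in sub.graph.edges} == edges

    def test_seed_order_independent(self):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        seeds = [0, 5, 10, 20]
        s1 = geodesic_subgraph(g, _seedset({s: "up" for s in seeds}))
        s2 = geodesic_subgraph(g, _seedset({s: "up" for s in reversed(seeds)}))
        assert set(s1.graph.nodes) == set(s2.graph.nodes)
        assert set(map(frozenset, s1.graph.edges)) == set(map(frozenset, s2.graph.edges))

    def test_disconnected_pair_skipped(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        sub = geodesic_subgraph(g, _seedset({"A": "up", "B": "up", "C": "down"}))
        assert set(sub.graph.nodes) == {"A", "B"}

    def test_subgraph_is_subset_of_ppi(self):
        g = nx.gnp_random_graph(40, 0.1, seed=4)
        sub = geodesic_subgraph(g, _seedset({0: "up", 1: "up", 2: "down", 3: "down"}))
        assert set(sub.graph.nodes) <= set(g.nodes)
        assert all(g.has_edge(u, v) for u, v in sub.graph.edges)


class TestRewireNull:
    def test_degree_sequence_preserved(self):
        g = nx.gnp_random_graph(50, 0.1, seed=5)
        for null in rewire_null(g, n_networks=3, seed=1):
            assert dict(null.degree) == dict(g.degree)
            assert nx.number_of_selfloops(null) == 0

    def test_triangle_unchanged(self):
        g = nx.complete_graph(3)
        nulls = rewire_null(g, n_networks=2, seed=2)
        for null in nulls:
            assert set(map(frozenset, null.edges)) == set(map(frozenset, g.edges))

    def test_mixing_on_er_graph(self):
        g = nx.gnp_random_graph(200, 0.05, seed=6)
        null = rewire_null(g, n_networks=1, swaps_per_edge=10, seed=3)[0]
        shared = set(map(frozenset, null.edges)) & set(map(frozenset, g.edges))
        assert len(shared) / g.number_of_edges() < 0.7

    def test_reproducible(self):
        g = nx.gnp_random_graph(40, 0.1, seed=7)
        n1 = rewire_null(g, n_networks=2, seed=9)
        n2 = rewire_null(g, n_networks=2, seed=9)
        for a, b in zip(n1, n2):
            assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError):
            rewire_null(nx.Graph([("A", "B")]))


def _all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


class TestLouvain:
    def test_two_cliques_match_exhaustive_optimum(self):
        g = nx.Graph()
        for base in (0, 4):
            for i, j in itertools.combinations(range(base, base + 4), 2):
                g.add_edge(i, j)
        g.add_edge(0, 4)
        cs = louvain_cluster(g, directions={}, seed=0)
        best_q = max(
            nx.community.modularity(g, [set(b) for b in part])
            for part in _all_partitions(list(g.nodes))
        )
        assert cs.modularity == pytest.approx(best_q)
        assert {frozenset(c) for c in cs.clusters} == {
            frozenset(range(4)),
            frozenset(range(4, 8)),
        }

    def test_disjoint_components_not_merged(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        cs = louvain_cluster(g, directions={}, seed=0)
        comps = [set(c) for c in nx.connected_components(g)]
        for cluster in cs.clusters:
            assert any(set(cluster) <= comp for comp in comps)

    def test_modularity_beats_trivial_partition(self):
        g = nx.gnp_random_graph(30, 0.2, seed=8)
        cs = louvain_cluster(g, directions={}, seed=0)
        assert cs.modularity >= 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_cluster(nx.Graph(), directions={})


class TestClusterActivity:
    @pytest.mark.parametrize(
        "dirs,expected",
        [
            ({"a": "up", "b": "up", "c": "up", "d": "down"}, (3, 1, 2, "up")),
            ({"a": "up", "b": "up", "c": "down", "d": "down"}, (2, 2, 0, "balanced")),
            ({"a": "none", "b": "none"}, (0, 0, 0, "balanced")),
        ],
    )
    def test_counts_and_label(self, dirs, expected):
        assert cluster_activity(set(dirs), dirs) == expected


class TestMatchClusters:
    def test_identical_partitions_diagonal(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        cs = louvain_cluster(g, directions={}, seed=0)
        mat, best = match_clusters(cs, cs)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert all(best[i][0] == i for i in best)

    def test_disjoint_node_sets_all_zero(self):
        g1 = nx.complete_graph(range(0, 4))
        g2 = nx.complete_graph(range(10, 14))
        c1 = louvain_cluster(g1, directions={}, seed=0)
        c2 = louvain_cluster(g2, directions={}, seed=0)
        mat, _ = match_clusters(c1, c2)
        assert np.allclose(mat.values, 0.0)


class TestNodeImportance:
    def test_star_graph_closed_form(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        sub = geodesic_subgraph(g, _seedset({1: "up", 2: "up", 3: "down", 4: "down"}))
        tab = node_importance(sub)
        assert tab.index[0] == 0
        assert tab.loc[0, "betweenness"] == pytest.approx(1.0)
        assert tab.loc[0, "importance"] == pytest.approx(4.0)
        assert np.allclose(tab.drop(index=0)["importance"], 0.0)

    def test_path_endpoints_zero(self):
        g = nx.path_graph(5)
        sub = geodesic_subgraph(g, _seedset({0: "up", 4: "down"}))
        tab = node_importance(sub)
        assert tab.loc[0, "importance"] == 0.0
        assert tab.loc[4, "importance"] == 0.0

    def test_matches_brute_force_betweenness(self):
        g = nx.gnp_random_graph(12, 0.3, seed=9)
        seeds = {n: "up" for n in list(g.nodes)[:4]}
        sub = geodesic_subgraph(g, _seedset(seeds))
        sg = sub.graph
        n = sg.number_of_nodes()
        # oracle: enumerate geodesics per pair, count pass-throughs
        brute = {v: 0.0 for v in sg.nodes}
        for s, t in itertools.combinations(sg.nodes, 2):
            try:
                paths = [
                    p
                    for p in nx.all_simple_paths(
                        sg, s, t, cutoff=nx.shortest_path_length(sg, s, t)
                    )
                    if len(p) - 1 == nx.shortest_path_length(sg, s, t)
                ]
            except nx.NetworkXNoPath:
                continue
            for v in sg.nodes:
                if v in (s, t):
                    continue
                frac = sum(v in p for p in paths) / len(paths)
                brute[v] += frac
        norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
        for v in sg.nodes:
            assert sub.nodes.loc[v, "betweenness"] == pytest.approx(brute[v] * norm)


class TestSubgraphEnrichment:
    def _graph(self):
        g = nx.gnp_random_graph(60, 0.1, seed=10)
        seeds = _seedset({n: "up" for n in list(g.nodes)[:4]})
        return g, seeds, geodesic_subgraph(g, seeds)

    def test_degenerate_significant_equals_subgraph(self):
        g, seeds, sub = self._graph()
        nonseed = set(sub.graph.nodes) - set(seeds.proteins)
        res = subgraph_enrichment(sub, nonseed, set(g.nodes), seeds)
        assert res.pval < 1e-6
        assert res.odds_ratio > 10

    def test_random_significant_has_unit_median_or(self):
        g, seeds, sub = self._graph()
        rng = np.random.default_rng(11)
        nonseed_n = len(set(sub.graph.nodes) - set(seeds.proteins))
        universe = sorted(set(g.nodes) - set(seeds.proteins))
        ors = []
        for _ in range(100):
            sig = set(rng.choice(universe, nonseed_n, replace=False))
            ors.append(subgraph_enrichment(sub, sig, set(g.nodes), seeds).odds_ratio)
        assert 0.5 < np.median(ors) < 2.0

    def test_null_sizes_give_empirical_p(self):
        g, seeds, sub = self._graph()
        res = subgraph_enrichment(
            sub, set(), set(g.nodes), seeds, null_sizes=[1, 2, 3, 100]
        )
        assert res.empirical_size_p == pytest.approx(2 / 5)
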