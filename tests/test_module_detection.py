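"""Module detection: cohesiveness formula, greedy growth, merge rules."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coregnet.module_detection import (
    DetectionParams,
    cohesiveness,
    detect_modules,
    grow_cluster,
    match_coefficient,
    merge_by_one_third_rule,
    module_from_genes,
    _merge_by_omega,
)
from tests.conftest import clique_edges, weighted_graph


def brute_force_cohesiveness(network: nx.Graph, genes: set, penalty: float) -> float:
    """Independent recomputation of f(V) straight from the edge list."""
    w_in = sum(d["weight"] for u, v, d in network.edges(data=True) if u in genes and v in genes)
    w_bound = sum(
        d["weight"] for u, v, d in network.edges(data=True) if (u in genes) != (v in genes)
    )
    denom = w_in + w_bound + penalty * len(genes)
    return 0.0 if denom == 0 else w_in / denom


def is_local_optimum(network: nx.Graph, genes: frozenset, penalty: float) -> bool:
    """No single connected add/remove strictly improves f."""
    f = brute_force_cohesiveness(network, set(genes), penalty)
    boundary = {nb for g in genes for nb in network[g]} - set(genes)
    for v in boundary:
        if brute_force_cohesiveness(network, set(genes) | {v}, penalty) > f + 1e-12:
            return False
    for v in genes:
        rest = set(genes) - {v}
        if rest and nx.is_connected(network.subgraph(rest)):
            if brute_force_cohesiveness(network, rest, penalty) > f + 1e-12:
                return False
    return True


class TestCohesiveness:
    def test_closed_triangle_is_one(self, triangle):
        assert cohesiveness(triangle, {"a", "b", "c"}, penalty=0.0) == pytest.approx(1.0)

    def test_two_of_triangle(self, triangle):
        # w_in = 1, w_bound = 2 -> 1/3
        assert cohesiveness(triangle, {"a", "b"}, penalty=0.0) == pytest.approx(1 / 3)

    def test_penalty_term(self, triangle):
        # 1 / (1 + 2 + 2*2) = 1/7
        assert cohesiveness(triangle, {"a", "b"}, penalty=2.0) == pytest.approx(1 / 7)

    def test_unknown_gene_rejected(self, triangle):
        with pytest.raises(KeyError):
            cohesiveness(triangle, {"a", "zzz"}, penalty=0.0)

    def test_empty_set_rejected(self, triangle):
        with pytest.raises(ValueError):
            cohesiveness(triangle, set(), penalty=0.0)


class TestGrowCluster:
    def test_recovers_clique_from_bridged_pair(self, two_cliques_bridge):
        params = DetectionParams(penalty=0.0)
        mod = grow_cluster(two_cliques_bridge, "a1", params)
        assert mod.genes == frozenset({"a0", "a1", "a2", "a3"})
        # f = 6 / (6 + 1): only the bridge leaves the clique
        assert mod.cohesiveness == pytest.approx(6 / 7)

    def test_isolated_edge_returns_both_endpoints(self):
        g = weighted_graph([("x", "y", 1.0)])
        mod = grow_cluster(g, "x", DetectionParams(penalty=0.0))
        assert mod.genes == frozenset({"x", "y"})
        assert mod.cohesiveness == pytest.approx(1.0)

    def test_growth_confined_to_connected_component(self):
        # a singleton has f = 0, so growth always absorbs at least one
        # neighbour, but can never leave the seed's component
        g = weighted_graph([("x", "y", 0.01), ("y", "z", 0.01), ("p", "q", 1.0)])
        mod = grow_cluster(g, "x", DetectionParams(penalty=100.0))
        assert frozenset({"x"}) < mod.genes <= frozenset({"x", "y", "z"})

    def test_undersized_clusters_discarded_by_min_size(self):
        g = weighted_graph([("x", "y", 0.5)])
        assert detect_modules(g, DetectionParams(min_size=3)) == []

    def test_result_is_local_optimum_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            g = nx.gnp_random_graph(9, 0.35, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
            for seed_node in list(g.nodes)[:4]:
                if g.degree(seed_node) == 0:
                    continue
                mod = grow_cluster(g, seed_node, DetectionParams(penalty=1.0))
                assert mod.cohesiveness == pytest.approx(
                    brute_force_cohesiveness(g, set(mod.genes), 1.0), abs=1e-12
                )
                assert is_local_optimum(g, mod.genes, 1.0)
                assert nx.is_connected(g.subgraph(mod.genes))


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g = weighted_graph(clique_edges(a) + clique_edges(b))
        mods = detect_modules(g, DetectionParams(penalty=0.5))
        assert len(mods) == 2
        assert {m.genes for m in mods} == {frozenset(a), frozenset(b)}

    def test_empty_network_yields_no_modules(self):
        assert detect_modules(nx.Graph(), DetectionParams()) == []

    def test_determinism(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.3, 1.0))
        mods1 = detect_modules(g, DetectionParams())
        mods2 = detect_modules(g, DetectionParams())
        assert mods1 == mods2

    def test_module_ids_are_sequential(self):
        a = [f"a{i}" for i in range(4)]
        b = [f"b{i}" for i in range(4)]
        g = weighted_graph(clique_edges(a) + clique_edges(b))
        mods = detect_modules(g, DetectionParams(penalty=0.5))
        assert [m.module_id for m in mods] == [1, 2]


class TestOmegaMerge:
    def test_match_coefficient_formula(self):
        a = frozenset("abcdef")
        b = frozenset("bcdefg")
        assert match_coefficient(a, b) == pytest.approx(25 / 36)

    def test_sharing_five_of_six_stays_below_threshold(self):
        """omega = 25/36 < 0.8, so two 6-sets sharing 5 members stay apart."""
        a = frozenset("abcdef")
        b = frozenset("bcdefg")
        assert _merge_by_omega([a, b], 0.8) == [a, b] or set(_merge_by_omega([a, b], 0.8)) == {a, b}
        merged = _merge_by_omega([a, b], 0.6)
        assert merged == [frozenset("abcdefg")]

    def test_transitive_union(self):
        a, b, c = frozenset("abcde"), frozenset("abcdf"), frozenset("abcfg")
        # omega(a,b)=omega(b,c)=16/25, omega(a,c)=9/25
        out = _merge_by_omega([a, b, c], 0.6)
        assert out == [frozenset("abcdefg")]


class TestOneThirdMerge:
    def _modules(self, network, *gene_sets):
        return [module_from_genes(network, s, 2.0, i + 1) for i, s in enumerate(gene_sets)]

    def _net_over(self, *gene_sets):
        g = nx.Graph()
        for s in gene_sets:
            nodes = sorted(s)
            for u, v in zip(nodes, nodes[1:]):
                g.add_edge(u, v, weight=1.0)
        return g

    def test_exact_one_third_boundary_not_merged(self):
        big = set("abcdefghi")  # 9 genes
        small = {"a", "x", "y"}  # overlap 1 = exactly 1/3 of 3
        net = self._net_over(big, small, big | small)
        mods = self._modules(net, big, small)
        out = merge_by_one_third_rule(mods, net)
        assert {m.genes for m in out} == {frozenset(big), frozenset(small)}

    def test_above_one_third_merged(self):
        big = set("abcdefghi")
        small = {"a", "b", "z"}  # overlap 2 > 1
        net = self._net_over(big, small, big | small)
        out = merge_by_one_third_rule(self._modules(net, big, small), net)
        assert {m.genes for m in out} == {frozenset(big | small)}

    def test_disjoint_modules_unchanged_any_order(self):
        s1, s2, s3 = set("abc"), set("def"), set("ghi")
        net = self._net_over(s1, s2, s3)
        expected = {frozenset(s1), frozenset(s2), frozenset(s3)}
        for perm in itertools.permutations([s1, s2, s3]):
            out = merge_by_one_third_rule(self._modules(net, *perm), net)
            assert {m.genes for m in out} == expected

    def test_fixed_point_and_overlap_bound(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(40)]
        sets = [set(rng.choice(universe, size=rng.integers(3, 12), replace=False))
                for _ in range(8)]
        net = self._net_over(*sets)
        out = merge_by_one_third_rule(self._modules(net, *sets), net)
        again = merge_by_one_third_rule(out, net)
        assert {m.genes for m in out} == {m.genes for m in again}
        for m1, m2 in itertools.combinations(out, 2):
            small = min(len(m1.genes), len(m2.genes))
            assert len(m1.genes & m2.genes) * 3 <= small

    def test_merged_cohesiveness_recomputed(self):
        big = set("abcdefghi")
        small = {"a", "b", "z"}
        net = self._net_over(big, small, big | small)
        (merged,) = merge_by_one_third_rule(self._modules(net, big, small), net, penalty=2.0)
        assert merged.cohesiveness == pytest.approx(
            brute_force_cohesiveness(net, set(merged.genes), 2.0), abs=1e-12
        )


class TestPlantedCliqueRecovery:
    def test_two_planted_cliques_recovered(self):
        """Smaller rehearsal of the planted-clique benchmark (2 replicates)."""
        from coregnet.synthetic_data import jaccard

        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            sizes = rng.integers(20, 41, size=2)
            names = [[f"c{k}_{i}" for i in range(s)] for k, s in enumerate(sizes)]
            edges = []
            for nodes in names:
                for i, u in enumerate(nodes):
                    for v in nodes[i + 1 :]:
                        edges.append((u, v, float(rng.uniform(0.5, 1.0))))
            for u in names[0]:
                for v in names[1]:
                    if rng.random() < 0.02:
                        edges.append((u, v, float(rng.uniform(0.5, 1.0))))
            g = weighted_graph(edges)
            mods = merge_by_one_third_rule(detect_modules(g, DetectionParams()), g)
            for nodes in names:
                best = max(jaccard(set(nodes), m.genes) for m in mods)
                assert best >= 0.9
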