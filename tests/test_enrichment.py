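"""Hypergeometric enrichment, weighted overlap null, and clique enumeration."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import draphnet as dn
from draphnet.enrichment import hypergeom_pvalue
from draphnet.errors import InvalidInputError


def brute_force_hypergeom(k, N, K, n):
    """P(X >= k) by exhaustive enumeration over all C(N, n) draws."""
    population = list(range(N))
    successes = set(range(K))
    hits = total = 0
    for draw in combinations(population, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_pvalue(0, 10, 3, 4) == pytest.approx(1.0)

    def test_closed_form_worked_example(self):
        # all 3 target drugs hit: C(3,3)/C(10,3) = 1/120
        assert hypergeom_pvalue(3, 10, 3, 3) == pytest.approx(1 / 120, rel=1e-12)

    @pytest.mark.parametrize("N", [5, 8, 12])
    def test_matches_brute_force_enumeration(self, N, rng):
        for _ in range(20):
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_pvalue(k, N, K, n) == pytest.approx(
                brute_force_hypergeom(k, N, K, n), abs=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            hypergeom_pvalue(4, 10, 3, 5)


class TestTargetGeneEnrichment:
    def test_counts_and_bh_within_target(self):
        targets = dn.TargetMap({"t1": {"d1", "d2", "d3"}, "tiny": {"d1"}})
        sets = dn.DrugGeneSets({
            "d1": {"gA", "gB"}, "d2": {"gA"}, "d3": {"gA"},
            "d4": {"gB"}, "d5": set(),
        })
        table = dn.target_gene_enrichment(targets, sets, n_drugs_total=5)
        # 'tiny' has < 3 drugs and is excluded
        assert set(table["target"]) == {"t1"}
        rowA = table[table["gene"] == "gA"].iloc[0]
        assert (rowA["k"], rowA["n"], rowA["K"], rowA["N"]) == (3, 3, 3, 5)
        assert rowA["p"] == pytest.approx(1 / 10)  # C(3,3)/C(5,3)
        # BH within target over the 2 tested genes
        from statsmodels.stats.multitest import multipletests
        expected_q = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(np.sort(table["q"]), np.sort(expected_q))


class TestPermutedTargetCalibration:
    def test_sizes_preserved_and_planted_target_detected(self, rng):
        drugs = [f"d{i}" for i in range(20)]
        gene_pool = [f"g{j}" for j in range(30)]
        sets = {
            d: set(rng.choice(gene_pool, size=4, replace=False)) for d in drugs
        }
        # planted: five drugs all share one gene
        for d in drugs[:5]:
            sets[d].add("shared_gene")
        targets = dn.TargetMap({"planted": set(drugs[:5]),
                                "random": set(drugs[10:14])})
        true_min, null_min = dn.permuted_target_calibration(
            targets, dn.DrugGeneSets(sets), n_drugs_total=20, n_perm=60, seed=0
        )
        assert set(null_min) == {"planted", "random"}
        assert len(null_min["planted"]) == 60
        # the planted target's min-p should sit in the low tail of its null
        frac_below = np.mean(null_min["planted"] <= true_min["planted"])
        assert frac_below < 0.1

    def test_independent_sets_are_calibrated(self, rng):
        drugs = [f"d{i}" for i in range(16)]
        gene_pool = [f"g{j}" for j in range(25)]
        sets = {d: set(rng.choice(gene_pool, size=3, replace=False)) for d in drugs}
        targets = dn.TargetMap({"t": set(drugs[:4])})
        true_min, null_min = dn.permuted_target_calibration(
            targets, dn.DrugGeneSets(sets), n_drugs_total=16, n_perm=80, seed=1
        )
        # under independence the true min-p is a typical draw from the null
        frac_below = np.mean(null_min["t"] <= true_min["t"])
        assert 0.01 < frac_below <= 1.0


class TestPairOverlapTest:
    def test_set_equal_to_universe_gives_one(self):
        universe = [f"g{i}" for i in range(5)]
        w = {g: 1 for g in universe}
        _, p = dn.pair_overlap_test(set(universe), {"g0", "g1"}, w, universe,
                                    n_sim=50, seed=0)
        assert p == pytest.approx(1.0)

    def test_zero_overlap_gives_one(self):
        universe = [f"g{i}" for i in range(6)]
        w = {g: 1 for g in universe}
        _, p = dn.pair_overlap_test({"g0"}, {"g5"}, w, universe, n_sim=50, seed=0)
        assert p == pytest.approx(1.0)

    def test_uniform_weights_converge_to_hypergeometric_tail(self):
        # |universe|=8, |A|=3, |B|=4, overlap 3: P(X>=3) = 4/56
        universe = [f"g{i}" for i in range(8)]
        w = {g: 1 for g in universe}
        A = {"g0", "g1", "g2"}
        B = {"g0", "g1", "g2", "g3"}
        n_sim = 10_000
        overlap, p = dn.pair_overlap_test(A, B, w, universe, n_sim=n_sim, seed=7)
        assert overlap == 3
        target = 4 / 56
        mc_se = np.sqrt(target * (1 - target) / n_sim)
        assert abs(p - target) < 3 * mc_se + 2 / n_sim

    def test_oversized_set_rejected(self):
        with pytest.raises(InvalidInputError):
            dn.pair_overlap_test({"a", "b"}, {"a"}, {"a": 1}, ["a"], n_sim=10)


class TestBuildNetwork:
    def test_identical_sets_over_weighted_universe_form_complete_graph(self, rng):
        shared = {f"s{i}" for i in range(6)}
        # a crowd of other drugs creates a large, unevenly weighted universe
        sets = {f"d{i}": set(shared) for i in range(4)}
        for i in range(30):
            sets[f"bg{i}"] = set(
                rng.choice([f"u{j}" for j in range(60)], size=6, replace=False)
            )
        net = dn.build_network(dn.DrugGeneSets(sets), p_threshold=0.05,
                               n_sim=200, seed=0)
        core = [f"d{i}" for i in range(4)]
        for a, b in combinations(core, 2):
            assert net.graph.has_edge(a, b)
        assert sorted(core) in net.cliques

    def test_disjoint_sets_give_no_edges(self):
        sets = {"a": {"g1", "g2"}, "b": {"g3", "g4"}, "c": {"g5"}}
        net = dn.build_network(dn.DrugGeneSets(sets), n_sim=50, seed=0)
        assert net.graph.number_of_edges() == 0

    def test_edge_annotations_match_direct_test(self):
        sets = {"a": {"g1", "g2", "g3"}, "b": {"g1", "g2", "g4"},
                "c": {"g5", "g6"}}
        gs = dn.DrugGeneSets(sets)
        net = dn.build_network(gs, p_threshold=1.01, n_sim=100, seed=3)
        from draphnet.enrichment import _pair_rng
        for a, b, data in net.graph.edges(data=True):
            small, big = sorted((sets[a], sets[b]), key=len)
            overlap, p = dn.pair_overlap_test(
                small, big, gs.gene_weight, gs.universe, n_sim=100,
                rng=_pair_rng(3, a, b),
            )
            assert data["overlap"] == overlap
            assert data["p"] == pytest.approx(p)

    def test_invariant_to_drug_input_order(self, rng):
        gene_pool = [f"g{j}" for j in range(20)]
        sets = {f"d{i}": set(rng.choice(gene_pool, size=5, replace=False))
                for i in range(8)}
        net1 = dn.build_network(dn.DrugGeneSets(sets), n_sim=100, seed=5)
        reversed_sets = dict(reversed(list(sets.items())))
        net2 = dn.build_network(dn.DrugGeneSets(reversed_sets), n_sim=100, seed=5)
        assert net1.edge_table().equals(net2.edge_table())


class TestFindCliques:
    @staticmethod
    def _net(edges, nodes=None):
        g = nx.Graph()
        if nodes:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return dn.DrugNetwork(graph=g, p_threshold=0.05)

    def test_triangle(self):
        net = self._net([("a", "b"), ("b", "c"), ("a", "c")])
        assert dn.find_cliques(net) == [["a", "b", "c"]]

    def test_path_has_no_cliques(self):
        net = self._net([("a", "b"), ("b", "c"), ("c", "d")])
        assert dn.find_cliques(net) == []

    def test_matches_exhaustive_enumeration(self, rng):
        def brute_force(graph, min_size):
            nodes = list(graph.nodes)
            out = []
            for r in range(min_size, len(nodes) + 1):
                for sub in combinations(nodes, r):
                    if all(graph.has_edge(u, v) for u, v in combinations(sub, 2)):
                        # maximal: no node outside connects to all members
                        if not any(
                            all(graph.has_edge(w, v) for v in sub)
                            for w in nodes if w not in sub
                        ):
                            out.append(sorted(sub))
            return sorted(out)

        for trial in range(100):
            g = nx.gnp_random_graph(12, 0.35, seed=trial)
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            net = dn.DrugNetwork(graph=g, p_threshold=0.05)
            assert dn.find_cliques(net) == brute_force(g, 3)


class TestVizGeneFilter:
    def test_significance_and_drug_count_rules(self):
        import pandas as pd

        sets = dn.DrugGeneSets({
            f"d{i}": {"g_popular"} for i in range(15)
        } | {"dx": {"g_rare", "g_never"}})
        table = pd.DataFrame({
            "target": ["t"] * 2,
            "gene": ["g_popular", "g_rare"],
            "q": [0.001, 0.001],
        })
        out = dn.viz_gene_filter(sets, table, max_drugs_per_gene=15)
        assert out == {"g_rare"}  # g_popular: 15 drugs (strict <); g_never: not significant

    def test_insignificant_gene_excluded(self):
        import pandas as pd

        sets = dn.DrugGeneSets({"d": {"g"}})
        table = pd.DataFrame({"target": ["t"], "gene": ["g"], "q": [0.5]})
        assert dn.viz_gene_filter(sets, table) == set()
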