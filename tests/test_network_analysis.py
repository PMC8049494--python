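"""Weighted-network connectivity: thresholds, shortest paths vs an exhaustive
path-enumeration oracle, set statistics, permutation nulls."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import twohit as th


def _edges(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


def path_enumeration_oracle(net, a, b):
    """Minimum inverse-weight path cost by enumerating all simple paths."""
    best = math.inf
    for path in nx.all_simple_paths(net, a, b):
        cost = sum(net[u][v]["cost"] for u, v in zip(path, path[1:]))
        best = min(best, cost)
    return best


class TestBuildNetwork:
    def test_absolute_cutoff_is_strict(self):
        net = th.build_network(_edges([("a", "b", 2.0), ("c", "d", 2.1)]), "absolute", 2.0)
        assert not net.has_edge("a", "b")
        assert net.has_edge("c", "d")

    def test_quantile_mode_keeps_top_fraction(self):
        rng = np.random.default_rng(0)
        w = rng.lognormal(0, 0.5, 1000)
        rows = [(f"u{i}", f"v{i}", wi) for i, wi in enumerate(w)]
        net = th.build_network(_edges(rows), "quantile", 0.005)
        assert net.number_of_edges() == 5

    def test_all_weights_below_cutoff_is_an_error(self):
        with pytest.raises(ValueError, match="empty network"):
            th.build_network(_edges([("a", "b", 1.0)]), "absolute", 2.0)

    def test_non_positive_weight_rejected_and_self_loops_dropped(self):
        with pytest.raises(ValueError, match="positive"):
            th.build_network(_edges([("a", "b", 0.0)]))
        net = th.build_network(_edges([("a", "a", 5.0), ("a", "b", 5.0)]), "absolute", 0.0)
        assert net.number_of_edges() == 1


class TestShortestPathConnectivity:
    def test_single_edge_pair(self):
        net = th.build_network(_edges([("A", "B", 4.0)]), "absolute", 0.0)
        q = th.shortest_path_connectivity(net, "A", "B")
        assert q.path_length == pytest.approx(0.25)
        assert q.connectivity == pytest.approx(4.0)
        assert q.connectors == ()

    def test_two_step_route_beats_weak_direct_edge(self, triangle_net):
        q = th.shortest_path_connectivity(triangle_net, "A", "C")
        assert q.path_length == pytest.approx(1.0)
        assert q.connectivity == pytest.approx(1.0)
        assert q.connectors == ("B",)

    def test_disconnected_pair_has_zero_connectivity(self):
        net = th.build_network(
            _edges([("A", "B", 1.0), ("C", "D", 1.0)]), "absolute", 0.0
        )
        q = th.shortest_path_connectivity(net, "A", "C")
        assert math.isinf(q.path_length)
        assert q.connectivity == 0.0
        assert q.connectors == ()

    def test_unknown_gene_rejected(self, triangle_net):
        with pytest.raises(KeyError):
            th.shortest_path_connectivity(triangle_net, "A", "Z")

    def test_tie_break_is_lexicographic_and_union_pools_all_paths(self):
        # two equal-cost routes A-B-D and A-C-D
        net = th.build_network(
            _edges([("A", "B", 1.0), ("B", "D", 1.0), ("A", "C", 1.0), ("C", "D", 1.0)]),
            "absolute",
            0.0,
        )
        q = th.shortest_path_connectivity(net, "A", "D")
        assert q.connectors == ("B",)
        q_union = th.shortest_path_connectivity(net, "A", "D", tie_mode="union")
        assert q_union.connectors == ("B", "C")

    def test_matches_exhaustive_path_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            rows = [
                (f"n{u}", f"n{v}", float(rng.uniform(0.2, 5.0)))
                for u, v in g.edges
            ]
            if not rows:
                continue
            net = th.build_network(_edges(rows), "absolute", 0.0)
            nodes = sorted(net.nodes)
            for a, b in itertools.combinations(nodes[:5], 2):
                q = th.shortest_path_connectivity(net, a, b)
                oracle = path_enumeration_oracle(net, a, b)
                if math.isinf(oracle):
                    assert q.connectivity == 0.0
                else:
                    assert q.path_length == pytest.approx(oracle)

    def test_connectivity_is_symmetric(self, triangle_net):
        for a, b in itertools.combinations(triangle_net.nodes, 2):
            qa = th.shortest_path_connectivity(triangle_net, a, b)
            qb = th.shortest_path_connectivity(triangle_net, b, a)
            assert qa.connectivity == pytest.approx(qb.connectivity)

    def test_adding_an_edge_never_decreases_connectivity(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(2**31)))
            rows = [(f"n{u}", f"n{v}", float(rng.uniform(0.2, 5.0))) for u, v in g.edges]
            if len(rows) < 2:
                continue
            net = th.build_network(_edges(rows), "absolute", 0.0)
            before = {
                (a, b): th.shortest_path_connectivity(net, a, b).connectivity
                for a, b in itertools.combinations(sorted(net.nodes), 2)
            }
            non_edges = [
                (a, b)
                for a, b in itertools.combinations(sorted(net.nodes), 2)
                if not net.has_edge(a, b)
            ]
            if not non_edges:
                continue
            a, b = non_edges[0]
            net.add_edge(a, b, weight=2.0, cost=0.5)
            for (x, y), c in before.items():
                after = th.shortest_path_connectivity(net, x, y).connectivity
                assert after >= c - 1e-12


class TestSetConnectivity:
    def test_two_genes_joined_by_one_edge(self):
        net = th.build_network(_edges([("A", "B", 4.0)]), "absolute", 0.0)
        res = th.set_connectivity(net, ["A", "B"], "mean")
        assert res.statistic == pytest.approx(4.0)
        assert th.set_connectivity(net, ["A", "B"], "median").statistic == pytest.approx(4.0)

    def test_path_graph_mean_over_all_pairs(self, path4_net):
        # pairwise connectivities {1, 1, 1, 1/2, 1/2, 1/3}
        res = th.set_connectivity(path4_net, list("abcd"), "mean")
        assert res.statistic == pytest.approx((3 + 0.5 + 0.5 + 1 / 3) / 6, abs=5e-4)
        assert round(res.statistic, 3) == 0.722

    def test_absent_genes_are_excluded_with_remaining_pairs_scored(self, path4_net):
        res = th.set_connectivity(path4_net, ["a", "b", "zz"], "mean")
        assert res.genes_excluded == ("zz",)
        assert res.statistic == pytest.approx(1.0)

    def test_fewer_than_two_present_genes_rejected(self, path4_net):
        with pytest.raises(ValueError, match="fewer than two"):
            th.set_connectivity(path4_net, ["a", "zz"], "mean")


class TestConnectorRvis:
    def _annotation(self, values):
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(values))],
                "chromosome": "chr1",
                "position": range(len(values)),
                "rvis_percentile": values,
            }
        )
        return th.GeneAnnotation(table)

    def test_identical_distributions_give_p_one(self):
        ann = self._annotation([10, 20, 30, 10, 20, 30])
        res = th.connector_rvis_comparison(["g0", "g1", "g2"], ["g3", "g4", "g5"], ann)
        assert res.p_value == 1.0

    def test_separated_rvis_sets(self):
        ann = self._annotation([5, 10, 15, 80, 85, 90])
        res = th.connector_rvis_comparison(["g0", "g1", "g2"], ["g3", "g4", "g5"], ann)
        assert res.p_value == pytest.approx(0.1)
        assert res.intolerant_fraction_a == 1.0
        assert res.intolerant_fraction_b == 0.0

    def test_missing_rvis_dropped_and_empty_set_rejected(self):
        ann = self._annotation([10, np.nan, np.nan])
        with pytest.raises(ValueError, match="empty"):
            th.connector_rvis_comparison(["g0"], ["g1", "g2"], ann)


class TestPermutationSampling:
    def test_sets_of_all_genes_are_the_full_gene_set(self, path4_net):
        sets = th.sample_random_sets(path4_net, 4, 5, seed=1)
        assert all(sorted(s) == ["a", "b", "c", "d"] for s in sets)

    def test_fixed_seed_reproduces_draws(self, path4_net):
        assert th.sample_random_sets(path4_net, 2, 10, seed=3) == th.sample_random_sets(
            path4_net, 2, 10, seed=3
        )

    def test_oversized_k_rejected(self, path4_net):
        with pytest.raises(ValueError):
            th.sample_random_sets(path4_net, 5, 1, seed=0)

    def test_singleton_draws_are_uniform(self):
        net = th.build_network(
            _edges([(f"g{i}", f"g{(i + 1) % 10}", 1.0) for i in range(10)]),
            "absolute",
            0.0,
        )
        draws = th.sample_random_sets(net, 1, 10_000, seed=5)
        counts = pd.Series([s[0] for s in draws]).value_counts()
        sigma = math.sqrt(10_000 * 0.1 * 0.9)
        assert ((counts - 1000).abs() <= 3 * sigma).all()

    def test_blocks_are_contiguous_and_avoid_cnv_genes(self, toy_annotation):
        genes = toy_annotation.genes
        admissible = {
            tuple(genes[i : i + 3])
            for i in range(8)
            if not toy_annotation.table["in_cnv"][i : i + 3].any()
        }
        blocks = th.sample_contiguous_blocks(toy_annotation, 3, 200, seed=2)
        assert {tuple(b) for b in blocks} <= admissible

    def test_cnv_exclusion_can_be_disabled(self, toy_annotation):
        blocks = th.sample_contiguous_blocks(
            toy_annotation, 3, 200, exclude_cnv=False, seed=2
        )
        flagged = set(toy_annotation.table[toy_annotation.table.in_cnv]["gene"])
        assert any(flagged & set(b) for b in blocks)

    def test_oversized_block_rejected(self, toy_annotation):
        with pytest.raises(ValueError, match="no chromosome"):
            th.sample_contiguous_blocks(toy_annotation, 11, 1)


class TestPermutationSummary:
    def test_extreme_observations_hit_percentile_bounds(self):
        null = [1.0, 2.0, 3.0]
        assert th.permutation_summary(0.5, null).percentile == 0.0
        assert th.permutation_summary(9.0, null).percentile == 100.0

    def test_z_score_uses_sample_standard_deviation(self):
        res = th.permutation_summary(5.0, [1, 2, 3, 4, 5], direction="higher")
        assert res.z == pytest.approx(2.0 / math.sqrt(2.5))
        assert round(res.z, 3) == 1.265

    def test_one_tailed_p_follows_direction(self):
        lower = th.permutation_summary(-2.0, [1, 2, 3, 4, 5], "lower")
        higher = th.permutation_summary(-2.0, [1, 2, 3, 4, 5], "higher")
        assert lower.one_tailed_p < 0.05 < higher.one_tailed_p
        assert lower.one_tailed_p + higher.one_tailed_p == pytest.approx(1.0)

    def test_degenerate_null_is_flagged(self):
        res = th.permutation_summary(1.0, [2.0, 2.0, 2.0])
        assert res.degenerate_null
        assert math.isnan(res.z)

    def test_percentile_counting_convention(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=200)
        obs = float(null[37])  # a value tied with one null entry
        res = th.permutation_summary(obs, null)
        upper = 100.0 * np.mean(null >= obs)
        assert res.percentile + upper >= 100.0 - 100.0 / len(null) - 1e-9


class TestPlantedModuleRecovery:
    def test_planted_module_beats_random_sets(self):
        cfg = th.NetworkSimulationConfig(
            n_genes=120,
            edge_density=0.06,
            planted_modules=(((0, 1, 2, 3, 4, 5), 3.0),),
            seed=8,
        )
        edges, modules = th.generate_network(cfg)
        net = th.build_network(edges, "absolute", 0.0)
        res = th.connectivity_permutation_test(
            net, modules[0], "random_sets", 300, "median", "higher", seed=9
        )
        assert res.percentile > 95.0
        assert res.one_tailed_p < 0.05
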