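import numpy as np
import pytest

from mstnetclass.graph_core import GraphDataset
from mstnetclass.gspan import (MinerConfig, SubgraphPattern, find_embeddings,
                               is_subgraph, min_dfs_code,
                               mine_frequent_subgraphs)
from mstnetclass.selection import (SelectionConfig, binary_subnetwork_features,
                                   frequency_difference, rebuild_network,
                                   select_discriminative)

from conftest import make_graph


def pattern_of(labels, edges, freq):
    g = make_graph(labels, edges)
    return SubgraphPattern(g, min_dfs_code(g), freq)


class TestFrequencyDifference:
    def test_basic_difference(self):
        p = pattern_of("AB", [(0, 1)], {"a": 0.8, "b": 0.2})
        assert frequency_difference(p, "a", "b") == pytest.approx(0.6)

    def test_equal_frequencies_score_zero(self):
        p = pattern_of("AB", [(0, 1)], {"a": 0.7, "b": 0.7})
        assert frequency_difference(p, "a", "b") == 0.0

    def test_symmetric_in_classes(self):
        p = pattern_of("AB", [(0, 1)], {"a": 0.1, "b": 0.9})
        assert frequency_difference(p, "a", "b") == pytest.approx(0.8)
        assert frequency_difference(p, "b", "a") == pytest.approx(0.8)

    def test_missing_class_rejected(self):
        p = pattern_of("AB", [(0, 1)], {"a": 0.5})
        with pytest.raises(ValueError, match="no frequency"):
            frequency_difference(p, "a", "b")

    def test_planted_population_score_from_realized_counts(
        self, planted_population
    ):
        """Empirical score equals the recount of supporting graphs."""
        pop = planted_population
        ds = pop.dataset
        target = pop.design.planted_patterns[0].as_graph()
        counts = {}
        for cls in ("patient", "control"):
            sub = ds.filter_class(cls)
            counts[cls] = sum(is_subgraph(target, g) for g in sub.graphs) / len(sub)
        p = SubgraphPattern(target, min_dfs_code(target), counts)
        expected = abs(counts["patient"] - counts["control"])
        assert frequency_difference(p, "patient", "control") == pytest.approx(
            expected
        )
        assert expected > 0.6  # planted gap 0.9 vs 0.1 survives sampling


class TestSelectDiscriminative:
    def patterns(self):
        return [
            pattern_of("AB", [(0, 1)], {"a": 0.9, "b": 0.3}),   # score 0.6
            pattern_of("BC", [(0, 1)], {"a": 0.7, "b": 0.7}),   # score 0.0
            pattern_of("CD", [(0, 1)], {"a": 0.5, "b": 0.2}),   # score 0.3
        ]

    def test_top_k_order(self):
        out = select_discriminative(
            self.patterns(), SelectionConfig("top_k", k=2), "a", "b"
        )
        assert [p.graph.label_pairs() for p in out] == [
            {("A", "B")}, {("C", "D")}
        ]

    def test_min_difference_mode(self):
        out = select_discriminative(
            self.patterns(),
            SelectionConfig("min_difference", min_diff=0.5),
            "a", "b",
        )
        assert len(out) == 1
        assert out[0].graph.label_pairs() == {("A", "B")}

    def test_tie_prefers_smaller_pattern(self):
        big = pattern_of("ABC", [(0, 1), (1, 2)], {"a": 0.8, "b": 0.2})
        small = pattern_of("XY", [(0, 1)], {"a": 0.8, "b": 0.2})
        out = select_discriminative(
            [big, small], SelectionConfig("top_k", k=2), "a", "b"
        )
        assert out[0].n_edges == 1

    def test_k_exceeding_pool_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="only 3 available"):
            out = select_discriminative(
                self.patterns(), SelectionConfig("top_k", k=10), "a", "b"
            )
        assert len(out) == 3

    def test_scores_non_increasing(self, planted_population):
        ds = planted_population.dataset
        patterns = mine_frequent_subgraphs(ds, MinerConfig(0.7), "patient")
        out = select_discriminative(
            patterns, SelectionConfig("top_k", k=len(patterns)),
            "patient", "control",
        )
        scores = [frequency_difference(p, "patient", "control") for p in out]
        assert scores == sorted(scores, reverse=True)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="no patterns"):
            select_discriminative([], SelectionConfig(), "a", "b")


class TestRebuildNetwork:
    def test_both_patterns_embedded_keeps_all_edges(self):
        g = make_graph("ABCD", [(0, 1), (1, 2), (2, 3)])
        sel = [
            pattern_of("AB", [(0, 1)], {}),
            pattern_of("BCD", [(0, 1), (1, 2)], {}),
        ]
        assert rebuild_network(g, sel).edges == g.edges

    def test_embedded_vs_union_rule_contrast(self):
        g = make_graph("ABC", [(0, 1), (1, 2)])
        sel = [pattern_of("ABD", [(0, 1), (1, 2)], {})]  # edges (A,B),(B,D)
        assert rebuild_network(g, sel, "embedded").n_edges == 0
        union = rebuild_network(g, sel, "union")
        assert union.label_pairs() == {("A", "B")}

    def test_embedded_rule_matches_embedding_image_oracle(self, rng):
        """Kept edges equal the union of embedded pattern edge images."""
        from oracles import random_labeled_graph

        for _ in range(30):
            g = random_labeled_graph(rng, 7, 0.4, 3)
            pat_g = random_labeled_graph(rng, 3, 0.8, 3, connected=True)
            if pat_g.n_edges == 0:
                continue
            sel = [SubgraphPattern(pat_g, min_dfs_code(pat_g), {})]
            rebuilt = rebuild_network(g, sel, "embedded")
            expected = set()
            for emb in find_embeddings(pat_g, g):
                for pu, pv in pat_g.edges:
                    hu, hv = emb[pu], emb[pv]
                    expected.add((hu, hv) if hu < hv else (hv, hu))
            assert rebuilt.edges == expected

    def test_output_subset_of_input_and_idempotent(self, planted_population):
        ds = planted_population.dataset
        patterns = mine_frequent_subgraphs(ds, MinerConfig(0.7), "patient")
        sel = select_discriminative(
            patterns, SelectionConfig("top_k", k=5), "patient", "control"
        )
        for g in ds.graphs[:10]:
            r1 = rebuild_network(g, sel)
            assert r1.edges <= g.edges
            assert r1.nodes == g.nodes
            r2 = rebuild_network(r1, sel)
            assert r2.edges == r1.edges

    def test_planted_pattern_tops_ranking_on_synthetic_data(
        self, planted_population
    ):
        """The planted subnetwork attains the maximum frequency difference."""
        pop = planted_population
        patterns = mine_frequent_subgraphs(
            pop.dataset, MinerConfig(0.7), "patient"
        )
        ranked = select_discriminative(
            patterns, SelectionConfig("top_k", k=len(patterns)),
            "patient", "control",
        )
        target_code = min_dfs_code(pop.design.planted_patterns[0].as_graph())
        rank = [i for i, p in enumerate(ranked) if p.code == target_code]
        assert rank and rank[0] < 5
        top_score = frequency_difference(ranked[0], "patient", "control")
        planted_score = frequency_difference(
            ranked[rank[0]], "patient", "control"
        )
        assert planted_score >= top_score - 0.1


class TestBinaryFeatures:
    def test_indicator_columns(self, planted_population):
        pop = planted_population
        ds = pop.dataset
        target = pop.design.planted_patterns[0].as_graph()
        sel = [SubgraphPattern(target, min_dfs_code(target), {})]
        fm = binary_subnetwork_features(ds, sel)
        assert fm.values.shape == (60, 1)
        assert set(np.unique(fm.values)) <= {0, 1}
        # column sums equal realized per-class support counts
        for cls in ("patient", "control"):
            idx = [i for i, c in enumerate(ds.class_labels) if c == cls]
            expected = sum(is_subgraph(target, ds.graphs[i]) for i in idx)
            assert fm.values[idx, 0].sum() == expected

    def test_ubiquitous_and_absent_patterns(self):
        g1 = make_graph("AB", [(0, 1)])
        g2 = make_graph("AB", [(0, 1)])
        ds = GraphDataset([g1, g2], ["x", "y"])
        present = pattern_of("AB", [(0, 1)], {})
        absent = pattern_of("CD", [(0, 1)], {})
        fm = binary_subnetwork_features(ds, [present, absent])
        assert fm.values[:, 0].tolist() == [1, 1]
        assert fm.values[:, 1].tolist() == [0, 0]

    def test_empty_selection_rejected(self, planted_population):
        with pytest.raises(ValueError, match="empty"):
            binary_subnetwork_features(planted_population.dataset, [])
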