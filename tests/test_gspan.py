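import numpy as np
import pytest

from mstnetclass.graph_core import GraphDataset, LabeledGraph
from mstnetclass.gspan import (CODE_KEY, MinerConfig, is_subgraph,
                               min_dfs_code, mine_frequent_subgraphs,
                               subgraph_frequency)

from conftest import make_graph
from oracles import (brute_force_frequent_subgraphs, brute_force_is_subgraph,
                     random_labeled_graph)


def random_dataset(rng, n_graphs=5, max_nodes=6, n_labels=3):
    graphs = [
        random_labeled_graph(
            rng, int(rng.integers(2, max_nodes + 1)), 0.5, n_labels
        )
        for _ in range(n_graphs)
    ]
    return GraphDataset(graphs, ["x"] * n_graphs)


class TestIsSubgraph:
    def test_edge_contained_in_path(self, single_edge, path_graph):
        assert is_subgraph(single_edge, path_graph)

    def test_missing_edge_not_contained(self):
        pattern = make_graph("ABC", [(0, 1), (1, 2)])
        host = make_graph("ABC", [(0, 1), (0, 2)])
        assert not is_subgraph(pattern, host)

    def test_empty_pattern_is_never_contained(self, path_graph):
        assert not is_subgraph(LabeledGraph({}), path_graph)

    def test_duplicate_label_pattern_needs_two_hosts(self):
        pattern = make_graph("AA", [(0, 1)])
        host_one_a = make_graph("AB", [(0, 1)])
        host_two_a = make_graph("AAB", [(0, 1)])
        assert not is_subgraph(pattern, host_one_a)
        assert is_subgraph(pattern, host_two_a)

    def test_agrees_with_brute_force_on_duplicate_labels(self, rng):
        """100 random (pattern, host) pairs vs exhaustive mapping search."""
        agreements = 0
        for _ in range(100):
            pattern = random_labeled_graph(rng, int(rng.integers(1, 5)), 0.6, 2)
            host = random_labeled_graph(rng, int(rng.integers(2, 7)), 0.5, 2)
            assert is_subgraph(pattern, host) == brute_force_is_subgraph(
                pattern, host
            )
            agreements += 1
        assert agreements == 100

    def test_unique_label_fast_path_agrees_with_generic(self, rng):
        """On unique-label trees both decision routes give one answer."""
        from mstnetclass.gspan import find_embeddings
        from mstnetclass.synthetic import PlantedDesign, generate_tree_population

        pop = generate_tree_population(
            PlantedDesign(n_per_class={"x": 10}, n_roi=8, seed=3)
        )
        pattern = make_graph([0, 1], [(0, 1)])  # labels are ROI indices
        for g in pop.dataset.graphs:
            fast = is_subgraph(pattern, g)
            generic = bool(find_embeddings(pattern, g, limit=1))
            assert fast == generic


class TestSubgraphFrequency:
    def make_three(self):
        g1 = make_graph("ABC", [(0, 1), (1, 2)])
        g2 = make_graph("ABC", [(0, 1), (0, 2)])
        g3 = make_graph("ABC", [(0, 1), (1, 2)])
        return GraphDataset([g1, g2, g3], ["a", "a", "b"])

    def test_ubiquitous_pattern(self, single_edge):
        assert subgraph_frequency(single_edge, self.make_three()) == 1.0

    def test_partial_pattern(self):
        bc = make_graph("BC", [(0, 1)])
        assert subgraph_frequency(bc, self.make_three()) == pytest.approx(2 / 3)

    def test_class_filtered_frequency(self):
        bc = make_graph("BC", [(0, 1)])
        ds = self.make_three()
        assert subgraph_frequency(bc, ds, "a") == pytest.approx(1 / 2)
        assert subgraph_frequency(bc, ds, "b") == 1.0

    def test_matches_brute_force_counts(self, rng):
        for _ in range(10):
            ds = random_dataset(rng)
            pattern = random_labeled_graph(rng, 3, 0.7, 3, connected=True)
            expected = (
                sum(brute_force_is_subgraph(pattern, g) for g in ds.graphs)
                / len(ds)
            )
            assert subgraph_frequency(pattern, ds) == pytest.approx(expected)


class TestMinDFSCode:
    def test_single_edge_orientation(self, single_edge):
        code = min_dfs_code(single_edge)
        assert len(code) == 1
        (i, j, li, _le, lj) = code[0]
        assert (i, j) == (0, 1) and (li, lj) == ("A", "B")

    def test_invariant_under_node_permutation(self, path_graph):
        permuted = path_graph.relabel_nodes({0: 2, 1: 0, 2: 1})
        assert min_dfs_code(path_graph) == min_dfs_code(permuted)

    def test_random_graphs_vs_isomorphism_referee(self, rng):
        """Equal codes iff isomorphic, refereed by a brute-force check."""
        from oracles import _isomorphic

        for _ in range(50):
            n = int(rng.integers(2, 7))
            g = random_labeled_graph(rng, n, 0.6, 2, connected=True)
            perm = rng.permutation(n)
            twin = g.relabel_nodes({i: int(perm[i]) for i in range(n)})
            assert min_dfs_code(g) == min_dfs_code(twin)
            other = random_labeled_graph(rng, n, 0.6, 2, connected=True)
            if min_dfs_code(other) == min_dfs_code(g):
                assert _isomorphic(other, g)
            else:
                assert not _isomorphic(other, g)

    def test_disconnected_rejected(self):
        g = make_graph("ABCD", [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            min_dfs_code(g)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            min_dfs_code(LabeledGraph({0: "A"}))


class TestMining:
    def test_three_graph_example_at_support_07(self):
        g1 = make_graph("ABC", [(0, 1), (1, 2)])
        g2 = make_graph("ABC", [(0, 1), (0, 2)])
        g3 = make_graph("ABC", [(0, 1), (1, 2)])
        ds = GraphDataset([g1, g2, g3], ["x", "x", "x"])
        patterns = mine_frequent_subgraphs(ds, MinerConfig(0.7))
        assert len(patterns) == 1
        assert patterns[0].graph.label_pairs() == {("A", "B")}
        assert patterns[0].frequency["x"] == 1.0

    def test_support_one_keeps_only_universal_patterns(self, rng):
        ds = random_dataset(rng)
        for p in mine_frequent_subgraphs(ds, MinerConfig(1.0)):
            assert all(is_subgraph(p.graph, g) for g in ds.graphs)

    @pytest.mark.parametrize("s", [0.4, 0.6, 0.8])
    def test_oracle_equivalence_random_datasets(self, rng, s):
        """Mined pattern sets match exhaustive enumeration, keyed by code."""
        for _ in range(12):
            ds = random_dataset(rng)
            mined = {p.code for p in mine_frequent_subgraphs(ds, MinerConfig(s))}
            expected = {
                min_dfs_code(g)
                for g in brute_force_frequent_subgraphs(ds.graphs, s)
            }
            assert mined == expected

    def test_antimonotonicity_of_mined_output(self, rng):
        """Every connected sub-pattern is at least as frequent."""
        ds = random_dataset(rng)
        patterns = mine_frequent_subgraphs(ds, MinerConfig(0.4))
        from oracles import enumerate_connected_subgraphs

        for p in patterns[:20]:
            f = subgraph_frequency(p.graph, ds)
            for sub in enumerate_connected_subgraphs(p.graph):
                assert subgraph_frequency(sub, ds) >= f - 1e-12

    def test_support_monotonicity(self, rng):
        ds = random_dataset(rng)
        low = {p.code for p in mine_frequent_subgraphs(ds, MinerConfig(0.4))}
        high = {p.code for p in mine_frequent_subgraphs(ds, MinerConfig(0.8))}
        assert high <= low

    def test_reported_patterns_are_connected_and_frequent(self, rng):
        ds = random_dataset(rng)
        for p in mine_frequent_subgraphs(ds, MinerConfig(0.6)):
            assert p.graph.is_connected()
            assert p.n_edges >= 1
            assert subgraph_frequency(p.graph, ds) >= 0.6 - 1e-12

    def test_output_sorted_by_size_then_code(self, rng):
        ds = random_dataset(rng)
        patterns = mine_frequent_subgraphs(ds, MinerConfig(0.4))
        keys = [(p.n_edges, CODE_KEY(p.code)) for p in patterns]
        assert keys == sorted(keys)

    def test_max_edges_cap(self, rng):
        ds = random_dataset(rng)
        for p in mine_frequent_subgraphs(ds, MinerConfig(0.4, max_edges=2)):
            assert p.n_edges <= 2

    def test_per_class_frequencies_annotated(self, planted_population):
        ds = planted_population.dataset
        patterns = mine_frequent_subgraphs(
            ds, MinerConfig(0.7), class_filter="patient"
        )
        assert patterns, "planted pattern should be frequent in patients"
        for p in patterns:
            assert set(p.frequency) == {"patient", "control"}

    def test_bad_support_rejected(self, rng):
        with pytest.raises(ValueError, match="min_support"):
            MinerConfig(0.0)
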