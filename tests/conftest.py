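import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mstnetclass.graph_core import LabeledGraph  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def path_graph():
    """Path A - B - C."""
    g = LabeledGraph({0: "A", 1: "B", 2: "C"})
    g.add_edge(0, 1)
    g.add_edge(1, 2)
    return g


@pytest.fixture
def single_edge():
    g = LabeledGraph({0: "A", 1: "B"})
    g.add_edge(0, 1)
    return g


def make_graph(labels, edges):
    g = LabeledGraph(dict(enumerate(labels)))
    for u, v in edges:
        g.add_edge(u, v)
    return g


@pytest.fixture
def planted_population():
    """Small two-group population with one enriched 3-edge pattern."""
    from mstnetclass.synthetic import generate_tree_population, two_class_design

    return generate_tree_population(two_class_design(n_per_class=30, seed=0))
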