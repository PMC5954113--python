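"""Discriminative subnetwork selection and network rebuilding.

A frequent pattern is discriminative when its occurrence frequency differs
between the two diagnostic groups; the larger the absolute frequency
difference, the stronger the discriminability.  Subject networks are then
rebuilt by deleting every edge that does not appear in any selected
discriminative subnetwork, preserving exactly the topology those
subnetworks explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .graph_core import GraphDataset, LabeledGraph
from .gspan import CODE_KEY, SubgraphPattern, find_embeddings, is_subgraph

__all__ = [
    "SelectionConfig",
    "BinaryFeatureMatrix",
    "frequency_difference",
    "select_discriminative",
    "rebuild_network",
    "binary_subnetwork_features",
]


@dataclass
class SelectionConfig:
    """Either keep the top ``k`` patterns or all with difference >= min_diff."""

    mode: str = "top_k"
    k: int = 50
    min_diff: float = 0.5

    def __post_init__(self):
        if self.mode not in ("top_k", "min_difference"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "top_k" and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode == "min_difference" and not (0 < self.min_diff <= 1):
            raise ValueError("min_diff must be in (0, 1]")


@dataclass
class BinaryFeatureMatrix:
    """Subjects x patterns indicator matrix: entry 1 iff pattern occurs."""

    values: np.ndarray
    pattern_index: list[SubgraphPattern]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.pattern_index):
            raise ValueError("feature matrix misaligned with pattern index")


def frequency_difference(
    pattern: SubgraphPattern, class_a: str, class_b: str
) -> float:
    """Absolute between-class frequency difference |f(a) - f(b)|."""
    for c in (class_a, class_b):
        if c not in pattern.frequency:
            raise ValueError(f"pattern carries no frequency for class {c!r}")
    return abs(pattern.frequency[class_a] - pattern.frequency[class_b])


def select_discriminative(
    patterns: Sequence[SubgraphPattern],
    config: SelectionConfig,
    class_a: str,
    class_b: str,
) -> list[SubgraphPattern]:
    """Rank patterns by frequency difference and keep the most discriminative.

    Output is sorted by descending score; ties prefer smaller patterns,
    then canonical DFS-code order, so selection is fully deterministic.
    """
    if not patterns:
        raise ValueError("no patterns to select from")
    scored = sorted(
        patterns,
        key=lambda p: (
            -frequency_difference(p, class_a, class_b),
            p.n_edges,
            CODE_KEY(p.code),
        ),
    )
    if config.mode == "min_difference":
        return [
            p
            for p in scored
            if frequency_difference(p, class_a, class_b) >= config.min_diff
        ]
    if config.k > len(scored):
        warnings.warn(
            f"requested top {config.k} patterns but only {len(scored)} available",
            stacklevel=2,
        )
    return scored[: config.k]


def rebuild_network(
    g: LabeledGraph,
    selected: Sequence[SubgraphPattern],
    rule: str = "embedded",
) -> LabeledGraph:
    """Delete edges of ``g`` appearing in no selected discriminative pattern.

    embedded (default): an edge survives iff some selected pattern embeds
    in ``g`` and the edge lies in the image of that embedding.  union: an
    edge survives iff its label pair occurs in any selected pattern,
    whether or not the whole pattern occurs in ``g`` (cheaper, looser).
    All nodes are retained, isolated or not.
    """
    if rule not in ("embedded", "union"):
        raise ValueError(f"unknown rebuild rule {rule!r}")
    keep: set[tuple[int, int]] = set()
    if rule == "union":
        wanted = set()
        for p in selected:
            wanted |= p.graph.label_pairs()
        for u, v in g.edges:
            la, lb = g.node_labels[u], g.node_labels[v]
            pair = tuple(sorted((la, lb), key=lambda x: (str(type(x)), str(x))))
            if pair in wanted:
                keep.add((u, v))
    else:
        for p in selected:
            for emb in find_embeddings(p.graph, g):
                for pu, pv in p.graph.edges:
                    hu, hv = emb[pu], emb[pv]
                    keep.add((hu, hv) if hu < hv else (hv, hu))
    out = LabeledGraph(g.node_labels)
    for u, v in keep:
        out.add_edge(u, v, g.edge_weights.get((u, v)))
    return out


def binary_subnetwork_features(
    dataset: GraphDataset, selected: Sequence[SubgraphPattern]
) -> BinaryFeatureMatrix:
    """Indicator features f_ij = 1 iff pattern j occurs in subject i's network.

    This is the baseline feature set used to quantify what kernel PCA adds:
    it records which discriminative subnetworks occur but discards how they
    sit in the surrounding topology.
    """
    if not selected:
        raise ValueError("selected pattern list is empty")
    values = np.zeros((len(dataset), len(selected)), dtype=int)
    for i, g in enumerate(dataset.graphs):
        for j, p in enumerate(selected):
            values[i, j] = int(is_subgraph(p.graph, g))
    return BinaryFeatureMatrix(values, list(selected))
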