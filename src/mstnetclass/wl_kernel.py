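"""Weisfeiler–Lehman subtree kernel over labeled networks.

Each refinement round replaces a node's label with a compression of (its
own label, the sorted multiset of its neighbors' labels).  The feature map
phi(G) counts label occurrences in every round 0..h, and the kernel is the
plain inner product k(G, H) = <phi(G), phi(H)>, so two networks are
similar when they share many identically-labeled subtree patterns.

Compressed labels live in a table shared across a whole dataset so the
same signature always maps to the same token; a table fitted on training
graphs can be reused for held-out graphs, where genuinely unseen
signatures receive fresh tokens that contribute nothing to cross products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import GraphDataset, LabeledGraph

__all__ = [
    "WLConfig",
    "WLCompressionTable",
    "WLFeatureMap",
    "KernelMatrix",
    "wl_refine",
    "wl_kernel_value",
    "wl_kernel_matrix",
    "wl_feature_maps",
]


@dataclass
class WLConfig:
    h: int = 5  # refinement iterations; 0 keeps original labels only
    normalize: bool = False

    def __post_init__(self):
        if self.h < 0:
            raise ValueError("h must be >= 0")


class WLCompressionTable:
    """Injective signature -> token dictionary, filled in first-seen order."""

    def __init__(self):
        self._map: dict[object, int] = {}

    def token(self, signature) -> int:
        if signature not in self._map:
            self._map[signature] = len(self._map)
        return self._map[signature]

    def __len__(self):
        return len(self._map)


@dataclass
class WLFeatureMap:
    """Per-iteration token counts; iteration totals all equal n_nodes."""

    counts: list[dict[int, int]] = field(default_factory=list)

    def dot(self, other: "WLFeatureMap") -> float:
        total = 0
        for mine, theirs in zip(self.counts, other.counts):
            if len(theirs) < len(mine):
                mine, theirs = theirs, mine
            total += sum(c * theirs.get(tok, 0) for tok, c in mine.items())
        return float(total)


@dataclass
class KernelMatrix:
    values: np.ndarray
    subject_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        if v.size and np.max(np.abs(v - v.T)) > 1e-8:
            raise ValueError("kernel matrix not symmetric")


def wl_refine(
    g: LabeledGraph,
    h: int,
    table: WLCompressionTable | None = None,
) -> WLFeatureMap:
    """Run h rounds of label refinement and count tokens per round.

    Iteration 0 counts the (compressed) original labels; iteration i+1
    labels are compressions of (current label, sorted neighbor labels).
    Pass a shared ``table`` when maps must be comparable across graphs.
    """
    if table is None:
        table = WLCompressionTable()
    # initial labels sorted-by-node for deterministic token assignment
    current = {
        u: table.token(("raw", str(g.node_labels[u])))
        for u in sorted(g.node_labels)
    }
    fmap = WLFeatureMap()

    def snapshot():
        counts: dict[int, int] = {}
        for tok in current.values():
            counts[tok] = counts.get(tok, 0) + 1
        fmap.counts.append(counts)

    snapshot()
    for _ in range(h):
        nxt = {}
        for u in sorted(current):
            sig = (current[u], tuple(sorted(current[v] for v in g.neighbors(u))))
            nxt[u] = table.token(sig)
        current = nxt
        snapshot()
    return fmap


def wl_feature_maps(
    graphs: list[LabeledGraph],
    h: int,
    table: WLCompressionTable | None = None,
) -> tuple[list[WLFeatureMap], WLCompressionTable]:
    """Feature maps for a graph collection under one compression table."""
    if table is None:
        table = WLCompressionTable()
    return [wl_refine(g, h, table) for g in graphs], table


def wl_kernel_value(
    g: LabeledGraph,
    hgraph: LabeledGraph,
    h: int,
    table: WLCompressionTable | None = None,
) -> float:
    """k(G, H) with h refinement iterations (shared compression table)."""
    maps, _ = wl_feature_maps([g, hgraph], h, table)
    return maps[0].dot(maps[1])


def wl_kernel_matrix(dataset: GraphDataset, config: WLConfig) -> KernelMatrix:
    """Full N x N kernel matrix over a dataset with one shared table."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 graphs for a kernel matrix")
    maps, _ = wl_feature_maps(dataset.graphs, config.h)
    n = len(maps)
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            k[i, j] = k[j, i] = maps[i].dot(maps[j])
    if config.normalize:
        d = np.sqrt(np.diag(k))
        d[d == 0] = 1.0
        k = k / np.outer(d, d)
    return KernelMatrix(k, list(dataset.subject_ids))


def cross_kernel(
    test_maps: list[WLFeatureMap], train_maps: list[WLFeatureMap]
) -> np.ndarray:
    """n_test x n_train kernel block for projecting held-out graphs."""
    return np.array([[tm.dot(trm) for trm in train_maps] for tm in test_maps])
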