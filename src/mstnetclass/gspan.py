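"""Frequent connected-subnetwork mining via gSpan.

Patterns are canonicalized by their minimum DFS code: a depth-first
traversal of a graph emits one 5-tuple ``(i, j, l_i, l_e, l_j)`` per edge
(``i``/``j`` are discovery indices, ``l``s are labels), and the
lexicographically smallest emittable sequence is identical for all members
of an isomorphism class.  Mining grows codes by rightmost extension only,
prunes non-minimal codes, and counts support per transaction: a graph
supports a pattern at most once regardless of how many embeddings it has.

Brain-network MSTs have unique node labels (each node is its ROI), which
makes embeddings unique and mining on 90-node trees tractable; the
machinery below nevertheless handles duplicate labels in full generality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cmp_to_key
from typing import Iterable, Optional, Sequence

from .graph_core import GraphDataset, LabeledGraph

__all__ = [
    "DFSCode",
    "MinerConfig",
    "SubgraphPattern",
    "is_subgraph",
    "find_embeddings",
    "subgraph_frequency",
    "min_dfs_code",
    "mine_frequent_subgraphs",
    "attach_class_frequencies",
]

EDGE_LABEL = 0  # MST edges are unlabeled; one dummy label fills the slot

DFSEdge = tuple[int, int, object, object, object]
DFSCode = tuple[DFSEdge, ...]


def _lkey(label) -> tuple:
    """Total order over heterogeneous label tokens (ints before strings)."""
    if isinstance(label, bool):
        return (2, str(label))
    if isinstance(label, (int, float)):
        return (0, label)
    return (1, str(label))


def _edge_cmp(a: DFSEdge, b: DFSEdge) -> int:
    """gSpan order on DFS-code edges (Yan & Han neighborhood ordering)."""
    ia, ja = a[0], a[1]
    ib, jb = b[0], b[1]
    fwd_a, fwd_b = ia < ja, ib < jb
    if (ia, ja) != (ib, jb):
        if fwd_a and fwd_b:
            if ja != jb:
                return -1 if ja < jb else 1
            return -1 if ia > ib else 1
        if (not fwd_a) and (not fwd_b):
            if ia != ib:
                return -1 if ia < ib else 1
            return -1 if ja < jb else 1
        if (not fwd_a) and fwd_b:  # backward before forward from same spot
            return -1 if ia < jb else 1
        return -1 if ja <= ib else 1
    la = (_lkey(a[2]), _lkey(a[3]), _lkey(a[4]))
    lb = (_lkey(b[2]), _lkey(b[3]), _lkey(b[4]))
    if la == lb:
        return 0
    return -1 if la < lb else 1


def _code_cmp(ca: Sequence[DFSEdge], cb: Sequence[DFSEdge]) -> int:
    for a, b in zip(ca, cb):
        c = _edge_cmp(a, b)
        if c:
            return c
    return (len(ca) > len(cb)) - (len(ca) < len(cb))


_EDGE_KEY = cmp_to_key(_edge_cmp)
CODE_KEY = cmp_to_key(_code_cmp)


@dataclass
class MinerConfig:
    """Mining parameters; the reference setting uses min_support = 0.7."""

    min_support: float = 0.7
    max_edges: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.min_support <= 1):
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")
        if self.max_edges is not None and self.max_edges < 1:
            raise ValueError("max_edges must be positive")


@dataclass
class SubgraphPattern:
    """A mined connected pattern with canonical code and class frequencies."""

    graph: LabeledGraph
    code: DFSCode
    frequency: dict[str, float] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.code)

    def label_edges(self) -> list[tuple[object, object]]:
        return sorted(self.graph.label_pairs(), key=lambda p: tuple(map(_lkey, p)))

    def __eq__(self, other):
        return isinstance(other, SubgraphPattern) and self.code == other.code

    def __hash__(self):
        return hash(self.code)


# ---------------------------------------------------------------------------
# Subgraph isomorphism (monomorphism: edges mapped onto edges, not induced)
# ---------------------------------------------------------------------------

def find_embeddings(
    pattern: LabeledGraph,
    host: LabeledGraph,
    limit: Optional[int] = None,
) -> list[dict[int, int]]:
    """All label-preserving injective maps of pattern into host.

    Each embedding maps pattern node id -> host node id such that every
    pattern edge lands on a host edge.  ``limit`` truncates the search.
    """
    if pattern.n_nodes == 0:
        return []
    p_nodes = sorted(pattern.nodes, key=lambda u: (-pattern.degree(u), u))
    # candidates by label
    host_by_label: dict[tuple, list[int]] = {}
    for v in sorted(host.nodes):
        host_by_label.setdefault(_lkey(host.node_labels[v]), []).append(v)

    embeddings: list[dict[int, int]] = []
    assignment: dict[int, int] = {}
    used: set[int] = set()

    def backtrack(k: int) -> bool:
        if k == len(p_nodes):
            embeddings.append(dict(assignment))
            return limit is not None and len(embeddings) >= limit
        u = p_nodes[k]
        for v in host_by_label.get(_lkey(pattern.node_labels[u]), ()):
            if v in used:
                continue
            ok = True
            for w in pattern.neighbors(u):
                if w in assignment and not host.has_edge(v, assignment[w]):
                    ok = False
                    break
            if not ok:
                continue
            assignment[u] = v
            used.add(v)
            if backtrack(k + 1):
                return True
            del assignment[u]
            used.discard(v)
        return False

    backtrack(0)
    return embeddings


def is_subgraph(pattern: LabeledGraph, host: LabeledGraph) -> bool:
    """True iff pattern occurs in host (label-preserving, edge-preserving).

    When both graphs have unique node labels — always the case for MST
    brain networks — occurrence reduces to containment of the edge set by
    label pairs, which is checked directly.
    """
    if pattern.n_nodes == 0:
        return False
    if pattern.n_nodes > host.n_nodes or pattern.n_edges > host.n_edges:
        return False
    if pattern.has_unique_labels() and host.has_unique_labels():
        host_labels = {_lkey(l) for l in host.node_labels.values()}
        if any(_lkey(l) not in host_labels for l in pattern.node_labels.values()):
            return False
        return pattern.label_pairs() <= host.label_pairs()
    return bool(find_embeddings(pattern, host, limit=1))


def subgraph_frequency(
    pattern: LabeledGraph,
    dataset: GraphDataset,
    class_filter: Optional[str] = None,
) -> float:
    """Fraction of (optionally class-filtered) graphs containing pattern."""
    ds = dataset.filter_class(class_filter) if class_filter else dataset
    if len(ds) == 0:
        raise ValueError("empty graph set after class filtering")
    return sum(is_subgraph(pattern, g) for g in ds.graphs) / len(ds)


# ---------------------------------------------------------------------------
# Minimum DFS code
# ---------------------------------------------------------------------------

def _rightmost_path(code: Sequence[DFSEdge]) -> list[int]:
    """Discovery indices from root to the rightmost vertex, via tree edges."""
    parent: dict[int, int] = {}
    rightmost = 1
    for i, j, *_ in code:
        if i < j:  # forward (tree) edge
            parent[j] = i
            rightmost = j
    path = [rightmost]
    while path[-1] in parent:
        path.append(parent[path[-1]])
    path.reverse()
    return path


class _Embedding:
    """Partial map of a DFS code into one graph."""

    __slots__ = ("gid", "nodes", "covered")

    def __init__(self, gid: int, nodes: list[int], covered: frozenset):
        self.gid = gid
        self.nodes = nodes          # dfs index -> graph node
        self.covered = covered      # graph edges already matched

    def extend(self, node: Optional[int], edge: tuple[int, int]) -> "_Embedding":
        nodes = self.nodes + [node] if node is not None else self.nodes
        return _Embedding(self.gid, nodes, self.covered | {edge})


def _extensions(emb: _Embedding, g: LabeledGraph, rmp: list[int]):
    """All legal rightmost extensions of one embedding.

    Yields (edge_tuple, host_node_or_None, host_edge): backward edges from
    the rightmost vertex to the rightmost path, and forward edges from any
    rightmost-path vertex to a fresh node.
    """
    nodes = emb.nodes
    on_path = [nodes[i] for i in rmp]
    rm_idx = rmp[-1]
    rm_node = nodes[rm_idx]
    in_emb = set(nodes)
    # backward: rightmost vertex -> earlier vertex on the rightmost path
    for idx in rmp[:-1]:
        tgt = nodes[idx]
        if g.has_edge(rm_node, tgt):
            he = (rm_node, tgt) if rm_node < tgt else (tgt, rm_node)
            if he not in emb.covered:
                yield (
                    (rm_idx, idx, g.node_labels[rm_node], EDGE_LABEL,
                     g.node_labels[tgt]),
                    None,
                    he,
                )
    # forward: any rightmost-path vertex -> node outside the embedding
    for pos, idx in enumerate(rmp):
        src = on_path[pos]
        for nb in g.neighbors(src):
            if nb in in_emb:
                continue
            he = (src, nb) if src < nb else (nb, src)
            if he in emb.covered:
                continue
            yield (
                (idx, len(nodes), g.node_labels[src], EDGE_LABEL,
                 g.node_labels[nb]),
                nb,
                he,
            )


def min_dfs_code(g: LabeledGraph) -> DFSCode:
    """Canonical minimum DFS code of a connected graph with >= 1 edge.

    Built greedily: keep every embedding realizing the minimal code prefix,
    at each step take the smallest legal rightmost extension over all of
    them.  Lexicographic code order makes the greedy choice globally
    optimal.
    """
    if g.n_edges == 0:
        raise ValueError("minimum DFS code requires at least one edge")
    if not g.is_connected():
        raise ValueError("minimum DFS code requires a connected graph")

    # seed: minimal first edge over both orientations of every graph edge
    best_first: Optional[DFSEdge] = None
    seeds: list[_Embedding] = []
    for u, v in sorted(g.edges):
        for a, b in ((u, v), (v, u)):
            t = (0, 1, g.node_labels[a], EDGE_LABEL, g.node_labels[b])
            c = -1 if best_first is None else _edge_cmp(t, best_first)
            if c < 0:
                best_first = t
                seeds = []
            if c <= 0:
                he = (a, b) if a < b else (b, a)
                seeds.append(_Embedding(0, [a, b], frozenset({he})))

    code: list[DFSEdge] = [best_first]  # type: ignore[list-item]
    embs = seeds
    while len(code) < g.n_edges:
        rmp = _rightmost_path(code)
        best: Optional[DFSEdge] = None
        grown: list[_Embedding] = []
        for emb in embs:
            for t, node, he in _extensions(emb, g, rmp):
                c = -1 if best is None else _edge_cmp(t, best)
                if c < 0:
                    best = t
                    grown = []
                if c <= 0:
                    grown.append(emb.extend(node, he))
        code.append(best)  # type: ignore[arg-type]
        embs = grown
    return tuple(code)


def code_to_graph(code: Sequence[DFSEdge]) -> LabeledGraph:
    """Materialize the pattern graph a DFS code describes."""
    labels: dict[int, object] = {}
    edges = []
    for i, j, li, _le, lj in code:
        labels[i] = li
        labels[j] = lj
        edges.append((i, j))
    g = LabeledGraph(labels)
    for u, v in edges:
        g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# Mining
# ---------------------------------------------------------------------------

def mine_frequent_subgraphs(
    dataset: GraphDataset,
    config: MinerConfig,
    class_filter: Optional[str] = None,
) -> list[SubgraphPattern]:
    """All connected patterns (>= 1 edge) frequent in the graph set.

    A pattern is frequent when the fraction of graphs containing it is at
    least ``config.min_support``.  Each isomorphism class is reported once,
    keyed by its minimum DFS code, annotated with its frequency in every
    class of the *full* dataset, and the output is sorted by (edge count,
    code).
    """
    ds = dataset.filter_class(class_filter) if class_filter else dataset
    if len(ds) == 0:
        raise ValueError("empty graph set after class filtering")
    n = len(ds)
    min_count = config.min_support * n - 1e-9
    graphs = ds.graphs

    # frequent single edges, canonical orientation
    first_embs: dict[DFSEdge, list[_Embedding]] = {}
    for gid, g in enumerate(graphs):
        for u, v in sorted(g.edges):
            lu, lv = g.node_labels[u], g.node_labels[v]
            if _lkey(lu) <= _lkey(lv):
                t: DFSEdge = (0, 1, lu, EDGE_LABEL, lv)
                a, b = u, v
            else:
                t = (0, 1, lv, EDGE_LABEL, lu)
                a, b = v, u
            he = (u, v)
            first_embs.setdefault(t, []).append(_Embedding(gid, [a, b], frozenset({he})))
            if lu == lv and a == u:  # symmetric edge: both orientations embed
                first_embs[t].append(_Embedding(gid, [b, a], frozenset({he})))

    results: list[SubgraphPattern] = []

    def support(embs: list[_Embedding]) -> int:
        return len({e.gid for e in embs})

    def grow(code: list[DFSEdge], embs: list[_Embedding]) -> None:
        # canonicality check prunes duplicate enumeration branches
        if tuple(code) != min_dfs_code(code_to_graph(code)):
            return
        results.append(SubgraphPattern(code_to_graph(code), tuple(code)))
        if config.max_edges is not None and len(code) >= config.max_edges:
            return
        rmp = _rightmost_path(code)
        buckets: dict[DFSEdge, list[_Embedding]] = {}
        for emb in embs:
            for t, node, he in _extensions(emb, graphs[emb.gid], rmp):
                buckets.setdefault(t, []).append(emb.extend(node, he))
        for t in sorted(buckets, key=_EDGE_KEY):
            if support(buckets[t]) >= min_count:
                grow(code + [t], buckets[t])

    for t in sorted(first_embs, key=_EDGE_KEY):
        if support(first_embs[t]) >= min_count:
            grow([t], first_embs[t])

    results.sort(key=lambda p: (p.n_edges, CODE_KEY(p.code)))
    attach_class_frequencies(results, dataset)
    return results


def attach_class_frequencies(
    patterns: Iterable[SubgraphPattern], dataset: GraphDataset
) -> None:
    """Annotate each pattern with its frequency in every dataset class."""
    by_class = {c: dataset.filter_class(c) for c in dataset.classes}
    for p in patterns:
        p.frequency = {
            c: sum(is_subgraph(p.graph, g) for g in sub.graphs) / len(sub)
            for c, sub in by_class.items()
        }
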