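"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — exhaustive enumeration, string
relabeling, permutation search — and shares no code with the package's
optimized paths.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx
import numpy as np

from mstnetclass.graph_core import LabeledGraph


# ---------------------------------------------------------------------------
# Maximum spanning tree by exhaustive enumeration
# ---------------------------------------------------------------------------

def brute_force_max_spanning_tree_weight(n: int, weights: dict) -> float:
    """Maximum total weight over all spanning trees of K_n (edge subsets).

    Tries every (n-1)-edge subset; a subset is a spanning tree iff its
    union-find merge performs exactly n-1 successful unions.
    """
    edges = list(weights)
    best = -np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = max(best, sum(weights[e] for e in subset))
    return best


# ---------------------------------------------------------------------------
# Subgraph monomorphism by exhaustive injective-mapping search
# ---------------------------------------------------------------------------

def brute_force_is_subgraph(pattern: LabeledGraph, host: LabeledGraph) -> bool:
    """Try every injective node assignment; no pruning beyond labels."""
    if pattern.n_nodes == 0 or pattern.n_nodes > host.n_nodes:
        return False
    p_nodes = sorted(pattern.nodes)
    h_nodes = sorted(host.nodes)
    for perm in itertools.permutations(h_nodes, len(p_nodes)):
        mapping = dict(zip(p_nodes, perm))
        if any(
            str(pattern.node_labels[u]) != str(host.node_labels[mapping[u]])
            for u in p_nodes
        ):
            continue
        if all(host.has_edge(mapping[u], mapping[v]) for u, v in pattern.edges):
            return True
    return False


# ---------------------------------------------------------------------------
# Frequent-subgraph mining by exhaustive connected-edge-subset enumeration
# ---------------------------------------------------------------------------

def _nx_labeled(g: LabeledGraph) -> nx.Graph:
    out = nx.Graph()
    for u, l in g.node_labels.items():
        out.add_node(u, label=str(l))
    out.add_edges_from(g.edges)
    return out


def _isomorphic(a: LabeledGraph, b: LabeledGraph) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match("label", None)
    return nx.is_isomorphic(_nx_labeled(a), _nx_labeled(b), node_match=nm)


def enumerate_connected_subgraphs(g: LabeledGraph) -> list[LabeledGraph]:
    """All connected edge-induced subgraphs with >= 1 edge."""
    edges = sorted(g.edges)
    out = []
    for r in range(1, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            nodes = {u for e in subset for u in e}
            sub = LabeledGraph({u: g.node_labels[u] for u in nodes}, subset)
            if sub.is_connected():
                out.append(sub)
    return out


def _invariant(g: LabeledGraph) -> tuple:
    """Cheap isomorphism invariant to bucket candidates before full checks."""
    pairs = sorted(
        tuple(sorted((str(g.node_labels[u]), str(g.node_labels[v]))))
        for u, v in g.edges
    )
    degs = sorted((str(g.node_labels[u]), g.degree(u)) for u in g.nodes)
    return (g.n_edges, tuple(pairs), tuple(degs))


def brute_force_frequent_subgraphs(
    graphs: list[LabeledGraph], min_support: float
) -> list[LabeledGraph]:
    """Frequent connected patterns by enumeration + isomorphism dedup.

    Each graph's connected subgraphs are enumerated once; isomorphism
    classes are found within invariant buckets, and a graph counts at most
    once toward a class's support (transaction counting).
    """
    buckets: dict[tuple, list[tuple[LabeledGraph, set[int]]]] = {}
    for gid, g in enumerate(graphs):
        for sub in enumerate_connected_subgraphs(g):
            key = _invariant(sub)
            for rep, supporters in buckets.setdefault(key, []):
                if _isomorphic(sub, rep):
                    supporters.add(gid)
                    break
            else:
                buckets[key].append((sub, {gid}))
    n = len(graphs)
    return [
        rep
        for classes in buckets.values()
        for rep, supporters in classes
        if len(supporters) / n >= min_support - 1e-12
    ]


# ---------------------------------------------------------------------------
# Naive Weisfeiler-Lehman subtree kernel (string labels, no compression)
# ---------------------------------------------------------------------------

def naive_wl_features(g: LabeledGraph, h: int) -> Counter:
    """Multiset of (iteration, label-string) pairs after h refinements."""
    labels = {u: str(g.node_labels[u]) for u in g.nodes}
    feats: Counter = Counter()
    for u in g.nodes:
        feats[(0, labels[u])] += 1
    for it in range(1, h + 1):
        new = {}
        for u in g.nodes:
            neigh = sorted(labels[v] for v in g.neighbors(u))
            new[u] = labels[u] + "|" + ",".join(neigh)
        labels = new
        for u in g.nodes:
            feats[(it, labels[u])] += 1
    return feats


def naive_wl_kernel(a: LabeledGraph, b: LabeledGraph, h: int) -> float:
    fa, fb = naive_wl_features(a, h), naive_wl_features(b, h)
    return float(sum(c * fb.get(key, 0) for key, c in fa.items()))


# ---------------------------------------------------------------------------
# Random graph generators for property tests
# ---------------------------------------------------------------------------

def random_labeled_graph(
    rng: np.random.Generator,
    n_nodes: int,
    edge_prob: float = 0.5,
    n_labels: int = 3,
    connected: bool = False,
) -> LabeledGraph:
    labels = {i: f"L{rng.integers(0, n_labels)}" for i in range(n_nodes)}
    g = LabeledGraph(labels)
    for u in range(n_nodes):
        for v in range(u + 1, n_nodes):
            if rng.random() < edge_prob:
                g.add_edge(u, v)
    if connected:
        comps = _components(g)
        while len(comps) > 1:
            a = comps[0][int(rng.integers(0, len(comps[0])))]
            b = comps[1][int(rng.integers(0, len(comps[1])))]
            g.add_edge(a, b)
            comps = _components(g)
    return g


def _components(g: LabeledGraph) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in sorted(g.nodes):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            for w in g.neighbors(stack.pop()):
                if w not in seen:
                    seen.add(w)
                    comp.append(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def random_complete_weights(rng: np.random.Generator, n: int) -> dict:
    return {
        (u, v): float(rng.uniform(-1, 1))
        for u in range(n)
        for v in range(u + 1, n)
    }
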