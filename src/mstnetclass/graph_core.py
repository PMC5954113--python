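"""Core domain types for labeled brain networks and their file formats.

A subject's brain network is an undirected graph whose nodes are atlas
regions of interest (ROIs).  Every node carries exactly one label token; in
the brain-network application the label of a node is its own ROI index, so
labels are unique within a graph, but the types below permit duplicate
labels so the miner and kernel stay fully general.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ROIAtlas",
    "LabeledGraph",
    "GraphDataset",
    "read_matrix",
    "read_graph",
    "write_graph",
    "read_manifest",
    "write_manifest",
]


class GraphFormatError(ValueError):
    """Raised for malformed graph or matrix files."""


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered universe of region names; internal node ids are 0..n-1."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if not self.labels:
            raise ValueError("atlas must contain at least one region")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas region names must be unique")

    @classmethod
    def default(cls, n_roi: int) -> "ROIAtlas":
        """Generic atlas ``ROI_0 .. ROI_{n-1}`` (the standard run uses 90)."""
        return cls(tuple(f"ROI_{i}" for i in range(n_roi)))

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def label(self, idx: int) -> str:
        return self.labels[idx]


def _norm_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


class LabeledGraph:
    """Undirected node-labeled graph, optionally edge-weighted.

    Nodes are integers, each with exactly one hashable label token.  Edges
    are unordered pairs without self-loops.  Equality ignores node identity:
    two graphs compare equal when a label-preserving bijection maps one edge
    set onto the other (cheap exact check when labels are unique; full
    isomorphism otherwise).
    """

    __slots__ = ("node_labels", "_edges", "edge_weights")

    def __init__(
        self,
        node_labels: Mapping[int, object],
        edges: Iterable[tuple[int, int]] = (),
        edge_weights: Mapping[tuple[int, int], float] | None = None,
    ):
        self.node_labels: dict[int, object] = dict(node_labels)
        self._edges: set[tuple[int, int]] = set()
        self.edge_weights: dict[tuple[int, int], float] = {}
        for u, v in edges:
            self.add_edge(u, v)
        if edge_weights:
            for (u, v), w in edge_weights.items():
                e = _norm_edge(u, v)
                if e not in self._edges:
                    self.add_edge(u, v)
                self.edge_weights[e] = float(w)

    # -- construction -----------------------------------------------------
    def add_edge(self, u: int, v: int, weight: float | None = None) -> None:
        if u == v:
            raise ValueError(f"self-loop ({u},{v}) not allowed")
        if u not in self.node_labels or v not in self.node_labels:
            raise ValueError(f"edge ({u},{v}) references unknown node")
        e = _norm_edge(u, v)
        self._edges.add(e)
        if weight is not None:
            self.edge_weights[e] = float(weight)

    # -- views -------------------------------------------------------------
    @property
    def nodes(self) -> set[int]:
        return set(self.node_labels)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return set(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, u: int, v: int) -> bool:
        return _norm_edge(u, v) in self._edges

    def neighbors(self, u: int) -> list[int]:
        return [b if a == u else a for a, b in self._edges if u in (a, b)]

    def degree(self, u: int) -> int:
        return sum(1 for e in self._edges if u in e)

    def label_pairs(self) -> set[tuple[object, object]]:
        """Edge set expressed as unordered label pairs (sorted by str)."""
        out = set()
        for u, v in self._edges:
            la, lb = self.node_labels[u], self.node_labels[v]
            out.add(tuple(sorted((la, lb), key=lambda x: (str(type(x)), str(x)))))
        return out

    def has_unique_labels(self) -> bool:
        return len(set(self.node_labels.values())) == len(self.node_labels)

    def is_connected(self) -> bool:
        if not self.node_labels:
            return True
        start = next(iter(self.node_labels))
        seen = {start}
        stack = [start]
        while stack:
            for w in self.neighbors(stack.pop()):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_nodes

    def copy(self) -> "LabeledGraph":
        return LabeledGraph(self.node_labels, self._edges, self.edge_weights)

    def relabel_nodes(self, mapping: Mapping[int, int]) -> "LabeledGraph":
        """Return a copy with node ids permuted through ``mapping``."""
        return LabeledGraph(
            {mapping[u]: l for u, l in self.node_labels.items()},
            {(mapping[u], mapping[v]) for u, v in self._edges},
            {
                _norm_edge(mapping[u], mapping[v]): w
                for (u, v), w in self.edge_weights.items()
            },
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for u, l in self.node_labels.items():
            g.add_node(u, label=l)
        for u, v in self._edges:
            if (u, v) in self.edge_weights:
                g.add_edge(u, v, weight=self.edge_weights[(u, v)])
            else:
                g.add_edge(u, v)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "LabeledGraph":
        labels = {int(u): d.get("label", u) for u, d in g.nodes(data=True)}
        out = cls(labels)
        for u, v, d in g.edges(data=True):
            out.add_edge(int(u), int(v), d.get("weight"))
        return out

    # -- equality ----------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledGraph):
            return NotImplemented
        if self.n_nodes != other.n_nodes or self.n_edges != other.n_edges:
            return False
        if sorted(map(str, self.node_labels.values())) != sorted(
            map(str, other.node_labels.values())
        ):
            return False
        if self.has_unique_labels() and other.has_unique_labels():
            return self.label_pairs() == other.label_pairs()
        nm = nx.algorithms.isomorphism.categorical_node_match("label", None)
        return nx.is_isomorphic(self.to_networkx(), other.to_networkx(), node_match=nm)

    def __hash__(self):  # labels + edge label pairs; coarse but consistent
        return hash(
            (
                frozenset((str(l), list(self.node_labels.values()).count(l))
                          for l in set(self.node_labels.values())),
                frozenset(self.label_pairs()),
            )
        )

    def __repr__(self):
        return f"LabeledGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class GraphDataset:
    """Aligned collection of subject graphs, class labels and subject ids."""

    graphs: list[LabeledGraph]
    class_labels: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:04d}" for i in range(len(self.graphs))]
        if not (len(self.graphs) == len(self.class_labels) == len(self.subject_ids)):
            raise ValueError("graphs, class_labels and subject_ids must align")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.class_labels:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "GraphDataset":
        return GraphDataset(
            [self.graphs[i] for i in indices],
            [self.class_labels[i] for i in indices],
            [self.subject_ids[i] for i in indices],
        )

    def filter_class(self, cls: str) -> "GraphDataset":
        idx = [i for i, c in enumerate(self.class_labels) if c == cls]
        if not idx:
            raise ValueError(f"class {cls!r} not present in dataset")
        return self.subset(idx)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(path)[1].lower()
    return "," if ext == ".csv" else "\t"


def read_matrix(path: str, delimiter: str | None = None):
    """Read a square symmetric connectivity matrix from delimited text.

    A header row of ROI names is detected automatically (first line whose
    cells are not all numeric).  Returns a ``ConnectivityMatrix``.
    """
    from .network_construction import ConnectivityMatrix

    delim = _sniff_delimiter(path, delimiter)
    with open(path) as fh:
        first = fh.readline()
    cells = [c.strip() for c in first.strip().split(delim) if c.strip() != ""]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = bool(cells) and not all(_numeric(c) for c in cells)
    names = cells if has_header else None
    try:
        df = pd.read_csv(
            path, sep=delim, header=0 if has_header else None, index_col=None
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GraphFormatError(f"cannot parse matrix file {path}: {exc}") from exc
    # drop a leading label column if present (row names mirroring the header)
    if has_header and df.shape[1] == df.shape[0] + 1:
        df = df.iloc[:, 1:]
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                if not _numeric(str(values[i, j])):
                    raise GraphFormatError(
                        f"non-numeric cell at row {i}, column {j}: {values[i, j]!r}"
                    )
        values = values.astype(float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise GraphFormatError(
            f"non-square matrix: shape {values.shape} in {path}"
        )
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > 1e-8:
        i, j = np.unravel_index(np.argmax(np.abs(values - values.T)), values.shape)
        raise GraphFormatError(
            f"matrix asymmetric beyond tolerance at ({i},{j}): "
            f"{values[i, j]} vs {values[j, i]}"
        )
    atlas = ROIAtlas(tuple(names)) if names else ROIAtlas.default(values.shape[0])
    return ConnectivityMatrix(np.asarray(values, dtype=float), atlas)


def write_graph(g: LabeledGraph, path: str, format: str = "edgelist") -> None:
    """Write a graph as an edge list (``u v [weight]`` lines) or GraphML.

    The edge-list dialect stores node labels in ``#label id token`` comment
    lines so that isolated nodes and label tokens survive the round trip.
    """
    if format == "edgelist":
        lines = ["# labeled undirected graph"]
        for u in sorted(g.node_labels):
            lines.append(f"#label {u} {g.node_labels[u]}")
        for u, v in sorted(g.edges):
            if (u, v) in g.edge_weights:
                lines.append(f"{u} {v} {g.edge_weights[(u, v)]!r}")
            else:
                lines.append(f"{u} {v}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(g.to_networkx(), path)
    else:
        raise ValueError(f"unknown graph format: {format!r}")


def _coerce_label(tok: str):
    try:
        return int(tok)
    except ValueError:
        return tok


def read_graph(path: str, format: str = "edgelist") -> LabeledGraph:
    """Inverse of :func:`write_graph`."""
    if format == "edgelist":
        labels: dict[int, object] = {}
        edges: list[tuple[int, int, float | None]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line.split()
                    if parts[0] == "#label" and len(parts) >= 3:
                        labels[int(parts[1])] = _coerce_label(parts[2])
                    continue
                parts = line.split()
                if len(parts) not in (2, 3):
                    raise GraphFormatError(
                        f"{path}:{lineno}: expected 'u v [weight]', got {line!r}"
                    )
                u, v = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) == 3 else None
                edges.append((u, v, w))
        for u, v, _ in edges:
            labels.setdefault(u, u)
            labels.setdefault(v, v)
        g = LabeledGraph(labels)
        for u, v, w in edges:
            g.add_edge(u, v, w)
        return g
    if format == "graphml":
        raw = nx.read_graphml(path)
        raw = nx.relabel_nodes(raw, {n: int(n) for n in raw.nodes})
        g = LabeledGraph.from_networkx(raw)
        g.node_labels = {u: _coerce_label(str(l)) for u, l in g.node_labels.items()}
        return g
    raise ValueError(f"unknown graph format: {format!r}")


def read_manifest(path: str, delimiter: str | None = None) -> list[tuple[str, str]]:
    """Read a two-column ``subject_id,class_label`` manifest."""
    delim = _sniff_delimiter(path, delimiter)
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'subject_id{delim}class', got {line!r}"
                )
            if lineno == 1 and parts[0].lower() in ("subject_id", "subject", "id"):
                continue
            out.append((parts[0], parts[1]))
    if not out:
        raise GraphFormatError(f"empty manifest: {path}")
    return out


def write_manifest(pairs: Sequence[tuple[str, str]], path: str) -> None:
    delim = "," if path.endswith(".csv") else "\t"
    with open(path, "w") as fh:
        for sid, cls in pairs:
            fh.write(f"{sid}{delim}{cls}\n")
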