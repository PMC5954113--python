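"""Subject-level network construction.

From an ROI time-series matrix we build the fully connected weighted
network of pairwise Pearson correlations, then reduce it either to its
maximum-weight spanning tree (Kruskal on descending weights — the method's
unbiased, threshold-free backbone) or to a binary network thresholded at a
fixed sparsity (the conventional baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import LabeledGraph, ROIAtlas

__all__ = [
    "ConnectivityMatrix",
    "correlation_network",
    "build_mst",
    "threshold_network",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI correlation matrix with its atlas."""

    values: np.ndarray
    roi_atlas: ROIAtlas

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {self.values.shape}")
        if self.values.shape[0] != len(self.roi_atlas):
            raise ValueError("matrix size does not match atlas size")
        if self.values.size and np.max(np.abs(self.values - self.values.T)) > 1e-8:
            raise ValueError("matrix asymmetric beyond 1e-8 tolerance")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


def correlation_network(timeseries: np.ndarray, atlas: ROIAtlas) -> ConnectivityMatrix:
    """Pearson-correlate ROI time courses into a fully connected network.

    ``timeseries`` is T x n_roi (one column per region).  Requires T >= 3
    and nonzero variance in every column.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D array (T x n_roi)")
    if ts.shape[0] < 3:
        raise ValueError(f"need at least 3 time points, got {ts.shape[0]}")
    if ts.shape[1] != len(atlas):
        raise ValueError("timeseries column count does not match atlas")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance time series for ROI {atlas.label(int(dead[0]))!r}"
        )
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0  # kill rounding asymmetry
    return ConnectivityMatrix(r, atlas)


def _candidate_edges(c: ConnectivityMatrix, weight_mode: str):
    """All off-diagonal pairs sorted by descending rank weight.

    Ties break on (min id, max id) ascending so results are reproducible.
    """
    if weight_mode not in ("signed", "absolute"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    n = c.n_roi
    iu, ju = np.triu_indices(n, k=1)
    w = c.values[iu, ju]
    if np.isnan(w).any():
        k = int(np.flatnonzero(np.isnan(w))[0])
        raise ValueError(f"NaN weight on edge ({iu[k]},{ju[k]})")
    rank = np.abs(w) if weight_mode == "absolute" else w
    order = sorted(range(len(w)), key=lambda k: (-rank[k], iu[k], ju[k]))
    return [(int(iu[k]), int(ju[k]), float(w[k])) for k in order]


def build_mst(c: ConnectivityMatrix, weight_mode: str = "signed") -> LabeledGraph:
    """Maximum-weight spanning tree via Kruskal on descending weights.

    Links are taken strongest-first; a link closing a cycle is skipped.
    The result has exactly n-1 edges, is connected and acyclic, and keeps
    the original correlation as the edge weight.  Node labels are the ROI
    indices (unique per graph).
    """
    n = c.n_roi
    if n < 2:
        raise ValueError("need at least 2 ROIs to build a spanning tree")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    g = LabeledGraph({i: i for i in range(n)})
    taken = 0
    for u, v, w in _candidate_edges(c, weight_mode):
        ru, rv = find(u), find(v)
        if ru == rv:
            continue
        parent[ru] = rv
        g.add_edge(u, v, w)
        taken += 1
        if taken == n - 1:
            break
    return g


def threshold_network(c: ConnectivityMatrix, sparsity: float,
                      weight_mode: str = "signed") -> LabeledGraph:
    """Binary network keeping the top ``round(sparsity * n(n-1)/2)`` edges.

    Uses round-half-to-even for the quota.  All nodes are present even if
    isolated; edges are unweighted (a kept link means weight above the
    implied threshold).
    """
    if not (0 < sparsity <= 1):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = c.n_roi
    n_pairs = n * (n - 1) // 2
    quota = int(np.round(sparsity * n_pairs))  # numpy rounds half to even
    g = LabeledGraph({i: i for i in range(n)})
    for u, v, _w in _candidate_edges(c, weight_mode)[:quota]:
        g.add_edge(u, v)
    return g
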