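"""Kernel PCA on a graph-kernel matrix.

The eigenproblem is lambda * alpha = K * alpha on the kernel matrix K.
Features for a network G are projections onto the top-m eigenvectors:
component m' of the feature vector is sum_i alpha_i^{m'} K(G_i, G), i.e. a
plain matrix–vector product of the retained eigenvectors with the row of
kernel values against the training networks.  The retained dimension m is
the smallest count whose absolute eigenvalue mass strictly exceeds 90% of
the total (a fixed m can be forced instead).

By default K enters the eigenproblem as-is; conventional double-centering
(removing the feature-space mean) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .wl_kernel import KernelMatrix

__all__ = ["KernelPCAModel", "kpca_fit", "choose_m", "kpca_transform"]


@dataclass
class KernelPCAModel:
    eigenvalues: np.ndarray        # sorted by |lambda| descending
    eigenvectors: np.ndarray       # column i pairs with eigenvalues[i]
    m: int
    centered: bool
    train_kernel: np.ndarray
    scale_by_sqrt_eigenvalue: bool = False

    @property
    def n_train(self) -> int:
        return self.train_kernel.shape[0]


def choose_m(eigenvalues: Sequence[float], mass: float = 0.9) -> int:
    """Smallest m with sum_{i<=m} |lambda_i| strictly > mass * total."""
    ev = np.abs(np.asarray(eigenvalues, dtype=float))
    total = ev.sum()
    if total == 0:
        raise ValueError("all-zero spectrum: cannot choose a dimension")
    cum = np.cumsum(ev)
    hits = np.flatnonzero(cum > mass * total)
    if hits.size == 0:  # numerically possible only at mass >= 1
        return len(ev)
    return int(hits[0]) + 1


def _center_train(k: np.ndarray) -> np.ndarray:
    n = k.shape[0]
    one = np.full((n, n), 1.0 / n)
    return k - one @ k - k @ one + one @ k @ one


def kpca_fit(
    kernel: KernelMatrix | np.ndarray,
    center: bool = False,
    m: Optional[int] = None,
    mass: float = 0.9,
    scale_by_sqrt_eigenvalue: bool = False,
) -> KernelPCAModel:
    """Eigendecompose K and fix the retained dimension.

    Eigenpairs are sorted by |lambda| descending (the retention rule sums
    absolute eigenvalues); eigenvectors have unit Euclidean norm.  ``m``
    overrides the eigenvalue-mass rule when given.
    """
    k = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel, float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("kernel matrix must be square")
    if k.size and np.max(np.abs(k - k.T)) > 1e-8:
        raise ValueError("kernel matrix not symmetric")
    raw = k.copy()
    if center:
        k = _center_train(k)
    evals, evecs = np.linalg.eigh((k + k.T) / 2.0)
    order = sorted(range(len(evals)), key=lambda i: (-abs(evals[i]), i))
    evals = evals[order]
    evecs = evecs[:, order]  # eigh returns unit-norm columns already
    if m is None:
        m = choose_m(evals, mass)
    m = min(m, len(evals))
    return KernelPCAModel(evals, evecs, m, center, raw, scale_by_sqrt_eigenvalue)


def kpca_transform(model: KernelPCAModel, k_rows: np.ndarray) -> np.ndarray:
    """Project kernel rows (graphs x training graphs) to m features.

    ``k_rows`` may be a single row of length N or an (n, N) block of rows;
    centering matches the fit.  Feature m' of a row is
    sum_i alpha_i^{m'} k_row[i].
    """
    rows = np.atleast_2d(np.asarray(k_rows, dtype=float))
    n = model.n_train
    if rows.shape[1] != n:
        raise ValueError(
            f"kernel row length {rows.shape[1]} != {n} training graphs"
        )
    if model.centered:
        k = model.train_kernel
        col_mean = k.mean(axis=0)
        rows = (
            rows
            - rows.mean(axis=1, keepdims=True)
            - col_mean[None, :]
            + k.mean()
        )
    alpha = model.eigenvectors[:, : model.m]
    if model.scale_by_sqrt_eigenvalue:
        lam = model.eigenvalues[: model.m]
        safe = np.where(np.abs(lam) > 1e-12, np.sqrt(np.abs(lam)), 1.0)
        alpha = alpha / safe[None, :]
    out = rows @ alpha
    return out[0] if np.asarray(k_rows).ndim == 1 else out
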