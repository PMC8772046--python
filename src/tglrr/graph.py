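"""k-nearest-neighbor sample graph and its Laplacian.

The manifold penalty Tr(Z L Zᵀ) forces the representation columns of
neighboring samples to stay close, preserving local geometric structure
of the sample cloud.  Graphs are stored dense: the sample count n is at
most a few thousand and the solver needs the dense spectral norm of L
anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SampleGraph:
    """Binary kNN weight matrix W, degree matrix O and Laplacian L = O - W."""

    W: NDArray[np.float64]
    O: NDArray[np.float64]
    L: NDArray[np.float64]
    k: int


def _sample_columns(X) -> NDArray[np.float64]:
    values = getattr(X, "values", X)
    A = np.asarray(values, dtype=float)
    if A.ndim != 2:
        raise ValueError("expression matrix must be 2-D (features x samples)")
    return A


def knn_weights(X, k: int, metric: str = "euclidean") -> NDArray[np.float64]:
    """Symmetric binary kNN adjacency over the columns (samples) of X.

    ``w_ij = 1`` iff sample i is among the k nearest neighbors of sample j
    or vice versa (the "or" rule makes W symmetric).  Distance ties are
    broken by column index via a stable sort, so the graph is
    deterministic even with duplicate points.
    """
    A = _sample_columns(X)
    n = A.shape[1]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n-1 (n={n})")
    D = cdist(A.T, A.T, metric=metric)
    np.fill_diagonal(D, np.inf)  # never pick self
    order = np.argsort(D, axis=0, kind="stable")
    W = np.zeros((n, n))
    cols = np.arange(n)
    for rank in range(k):
        W[order[rank], cols] = 1.0
    W = np.maximum(W, W.T)  # "or" rule; defensive symmetrization
    np.fill_diagonal(W, 0.0)
    return W


def build_graph(X, k: int, metric: str = "euclidean") -> SampleGraph:
    """Assemble W, the diagonal degree matrix O and the Laplacian L = O - W."""
    W = knn_weights(X, k, metric=metric)
    O = np.diag(W.sum(axis=1))
    return SampleGraph(W=W, O=O, L=O - W, k=k)


def graph_penalty(Z: ArrayLike, L: ArrayLike) -> float:
    """Manifold penalty Tr(Z L Zᵀ) = ½ Σ_ij w_ij ||z_i − z_j||²  (≥ 0)."""
    Z = np.asarray(Z, dtype=float)
    L = np.asarray(L, dtype=float)
    if Z.shape[1] != L.shape[0] or L.shape[0] != L.shape[1]:
        raise ValueError(
            f"shape mismatch: Z has {Z.shape[1]} columns, L is {L.shape}"
        )
    return float(np.trace(Z @ L @ Z.T))
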