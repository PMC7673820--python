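"""Symmetrized k-nearest-neighbor graph over cells and its Laplacian.

The graph is built on the expression feature space with Euclidean distance:
v_ij = 1 if i is among the k nearest neighbors of j or vice versa (OR
symmetrization), v_ii = 0.  With degree matrix D = diag(d), d_i = sum_j v_ij,
the (combinatorial, unnormalized) Laplacian is L = D - V.  The manifold
penalty tying neighboring cells to similar factor profiles is

    R1 = 1/2 sum_ij sum_z (h_iz - h_jz)^2 v_ij = trace(H^T L H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import ExpressionMatrix, feature_matrix

__all__ = ["NeighborGraph", "knn_graph", "graph_penalty"]


@dataclass
class NeighborGraph:
    """Binary symmetric KNN adjacency with degrees and Laplacian."""

    adjacency: np.ndarray
    degrees: np.ndarray
    laplacian: np.ndarray
    k_used: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


def knn_graph(x: ExpressionMatrix | np.ndarray, k: int = 10) -> NeighborGraph:
    """Exact Euclidean KNN graph, OR-symmetrized, self-edges excluded.

    Neighbor ranking uses a stable argsort so ties between equidistant
    points resolve deterministically by index order.
    """
    feats = x if isinstance(x, np.ndarray) else feature_matrix(x)
    feats = np.asarray(feats, dtype=float)
    n = feats.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}, got {k}")
    dist = cdist(feats, feats)
    np.fill_diagonal(dist, np.inf)  # exclude self
    order = np.argsort(dist, axis=1, kind="stable")
    neighbors = order[:, :k]
    adjacency = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    adjacency[rows, neighbors.ravel()] = 1.0
    adjacency = np.maximum(adjacency, adjacency.T)  # OR symmetrization
    degrees = adjacency.sum(axis=1)
    laplacian = np.diag(degrees) - adjacency
    return NeighborGraph(
        adjacency=adjacency, degrees=degrees, laplacian=laplacian, k_used=k
    )


def graph_penalty(h: np.ndarray, g: NeighborGraph) -> float:
    """R1 = trace(H^T L H); zero iff neighboring rows of H coincide."""
    h = np.asarray(h, dtype=float)
    if h.shape[0] != g.n_cells:
        raise ValueError(
            f"factor matrix has {h.shape[0]} rows but graph has {g.n_cells} nodes"
        )
    return float(np.trace(h.T @ g.laplacian @ h))
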