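"""Pre-learning of ensemble weights and assembly of the consensus matrix.

Each base clustering is turned into a binary co-membership matrix B_p
(b_ij = 1 iff cells i and j share a cluster).  Base methods are scored with
the Calinski-Harabasz index computed on the expression feature space, the
scores are normalized into weights u_p (0 < u_p < 1, sum 1), and the weighted
sum W = sum_p u_p B_p is thresholded into the binary consensus the
factorization consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, PartitionLabels, feature_matrix

__all__ = [
    "CoMembershipMatrix",
    "EnsembleWeights",
    "ConsensusMatrix",
    "labels_to_comembership",
    "calinski_harabasz",
    "normalize_weights",
    "assemble_consensus",
    "binarize_consensus",
]


@dataclass
class CoMembershipMatrix:
    """Binary symmetric n x n co-membership matrix of one base partition."""

    values: np.ndarray
    method_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("co-membership matrix must be square")


@dataclass
class EnsembleWeights:
    """Calinski-Harabasz scores and their normalized weights, one per method."""

    scores: np.ndarray
    weights: np.ndarray
    method_names: list[str] | None = None


@dataclass
class ConsensusMatrix:
    """Weighted (entries in [0,1]) or binarized consensus co-clustering matrix."""

    values: np.ndarray
    binarized: bool = False
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("consensus matrix must be square")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def labels_to_comembership(p: PartitionLabels) -> CoMembershipMatrix:
    """b_ij = 1 iff cells i and j carry the same label (diagonal 1)."""
    codes = p.as_codes()
    values = (codes[:, None] == codes[None, :]).astype(float)
    return CoMembershipMatrix(values=values, method_name=p.method_name)


def calinski_harabasz(
    x: ExpressionMatrix | np.ndarray,
    p: PartitionLabels,
    variant: str = "standard",
) -> float:
    """Calinski-Harabasz score of a partition on the expression feature space.

    ``variant="standard"`` is the usual variance-ratio criterion

        CH = [sum_k |C_k| ||z_k - z||^2 / (K-1)] / [sum_k sum_{x in C_k}
             ||x - z_k||^2 / (N-K)]

    with cluster centroids z_k and global centroid z.  ``variant="paper"``
    drops the |C_k| weighting of the between-cluster scatter and inverts the
    degrees-of-freedom factor to (K-1)/(N-K); it is retained only for
    reproducing results computed with that formula.  Only the ranking of
    base methods matters downstream, and the standard form ranks correctly.
    """
    feats = x if isinstance(x, np.ndarray) else feature_matrix(x)
    feats = np.asarray(feats, dtype=float)
    if feats.shape[0] != len(p):
        raise ValueError("feature matrix and partition disagree on cell count")
    codes = p.as_codes()
    n, k = feats.shape[0], int(codes.max()) + 1
    if k < 2:
        raise ValueError("Calinski-Harabasz needs at least 2 clusters")
    if n <= k:
        raise ValueError("Calinski-Harabasz needs more points than clusters")
    grand = feats.mean(axis=0)
    between_w = 0.0  # size-weighted between-cluster scatter
    between_u = 0.0  # unweighted variant
    within = 0.0
    for c in range(k):
        members = feats[codes == c]
        centroid = members.mean(axis=0)
        sep = float(np.sum((centroid - grand) ** 2))
        between_w += len(members) * sep
        between_u += sep
        within += float(np.sum((members - centroid) ** 2))
    if within == 0.0:
        raise ValueError("zero within-cluster scatter; CH is undefined")
    if variant == "standard":
        return (between_w / (k - 1)) / (within / (n - k))
    if variant == "paper":
        return (between_u / within) * (k - 1) / (n - k)
    raise ValueError(f"unknown CH variant {variant!r}")


def normalize_weights(
    scores: Sequence[float], method_names: list[str] | None = None
) -> EnsembleWeights:
    """u_p = CH_p / sum_q CH_q; requires strictly positive scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D sequence")
    if np.any(scores <= 0):
        raise ValueError("all scores must be strictly positive")
    return EnsembleWeights(
        scores=scores, weights=scores / scores.sum(), method_names=method_names
    )


def assemble_consensus(
    bs: Sequence[CoMembershipMatrix], w: EnsembleWeights
) -> ConsensusMatrix:
    """W = sum_p u_p B_p — the weighted co-clustering evidence."""
    if len(bs) != len(w.weights):
        raise ValueError(f"{len(bs)} matrices but {len(w.weights)} weights")
    n = bs[0].values.shape[0]
    for b in bs:
        if b.values.shape[0] != n:
            raise ValueError("co-membership matrices differ in size")
    values = np.zeros((n, n))
    for b, u in zip(bs, w.weights):
        values += u * b.values
    return ConsensusMatrix(values=values, binarized=False)


def binarize_consensus(w: ConsensusMatrix, wt: float = 0.5) -> ConsensusMatrix:
    """Threshold at wt: an entry becomes 1 iff strictly greater than wt.

    Strict inequality encodes "more than half of the methods agree" at the
    default wt = 0.5.  The diagonal is forced to 1.
    """
    if w.binarized:
        raise ValueError("consensus matrix is already binarized")
    if not (0.0 < wt < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {wt}")
    values = (w.values > wt).astype(float)
    np.fill_diagonal(values, 1.0)
    return ConsensusMatrix(values=values, binarized=True, threshold_used=wt)
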