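"""Hard cluster assignments and the automatically selected cluster count.

Each cell is assigned to the latent column with the largest entry of its row
of H*; the number of distinct columns actually used is the cluster count C.
ARD pruning makes unused columns vanish, so C adapts to the data rather than
to the (generous) upper bound Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PartitionLabels

__all__ = ["ClusterAssignment", "assign_clusters"]


@dataclass
class ClusterAssignment:
    """1-based consecutive cluster labels plus provenance of each label."""

    cell_ids: list[str]
    labels: list[int]
    n_clusters: int
    source_columns: list[int] = field(default_factory=list)
    low_confidence: list[str] = field(default_factory=list)

    def to_partition(self, method_name: str = "consensus") -> PartitionLabels:
        return PartitionLabels(
            cell_ids=list(self.cell_ids),
            labels=list(self.labels),
            method_name=method_name,
        )


def assign_clusters(
    h_star: np.ndarray,
    prune_tol: float = 1e-4,
    cell_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Argmax extraction from a fitted factor matrix.

    Ties break to the lowest column index (np.argmax's convention).  Used
    columns are relabeled 1..C in order of first appearance.  Rows whose
    entries are all <= prune_tol are still assigned but flagged as
    low-confidence.
    """
    h_star = np.asarray(h_star, dtype=float)
    n = h_star.shape[0]
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    if len(cell_ids) != n:
        raise ValueError("cell_ids length does not match factor matrix rows")
    argmax = np.argmax(h_star, axis=1)
    column_to_label: dict[int, int] = {}
    source_columns: list[int] = []
    labels: list[int] = []
    for col in argmax:
        col = int(col)
        if col not in column_to_label:
            column_to_label[col] = len(column_to_label) + 1
            source_columns.append(col)
        labels.append(column_to_label[col])
    low_confidence = [
        cell_ids[i] for i in range(n) if np.max(h_star[i]) <= prune_tol
    ]
    return ClusterAssignment(
        cell_ids=list(cell_ids),
        labels=labels,
        n_clusters=len(column_to_label),
        source_columns=source_columns,
        low_confidence=low_confidence,
    )
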