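"""External validation indices: adjusted Rand index and normalized mutual
information, computed from the contingency table of two partitions.

Both are implemented directly so the conventions are explicit: natural
logarithms (the base cancels in the NMI ratio), 0 * log 0 = 0, and NMI
normalized by the arithmetic mean of the two entropies,
NMI = 2 I(P1; P2) / (H(P1) + H(P2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PartitionLabels

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "adjusted_rand_index",
    "normalized_mutual_information",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    total: int


def _aligned_codes(p1: PartitionLabels, p2: PartitionLabels) -> tuple[np.ndarray, np.ndarray]:
    if set(p1.cell_ids) != set(p2.cell_ids):
        raise ValueError("partitions cover different cell sets")
    if p1.cell_ids != p2.cell_ids:
        p2 = p2.reorder(p1.cell_ids)
    return p1.as_codes(), p2.as_codes()


def contingency_table(p1: PartitionLabels, p2: PartitionLabels) -> ContingencyTable:
    """n_ij = number of cells in cluster i of p1 and cluster j of p2."""
    c1, c2 = _aligned_codes(p1, p2)
    k1, k2 = int(c1.max()) + 1, int(c2.max()) + 1
    counts = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(counts, (c1, c2), 1)
    return ContingencyTable(
        counts=counts,
        row_sums=counts.sum(axis=1),
        col_sums=counts.sum(axis=0),
        total=int(counts.sum()),
    )


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(p1: PartitionLabels, p2: PartitionLabels) -> float:
    """Chance-adjusted pair-counting agreement; 1 for identical partitions."""
    t = contingency_table(p1, p2)
    sum_ij = float(_comb2(t.counts.astype(float)).sum())
    sum_a = float(_comb2(t.row_sums.astype(float)).sum())
    sum_b = float(_comb2(t.col_sums.astype(float)).sum())
    pairs = float(_comb2(np.array(t.total, dtype=float)))
    expected = sum_a * sum_b / pairs
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:  # both partitions trivial (all-singletons or one block)
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def normalized_mutual_information(p1: PartitionLabels, p2: PartitionLabels) -> float:
    """2 I / (H1 + H2) with natural logs; zero-probability terms contribute 0."""
    t = contingency_table(p1, p2)
    n = t.total
    pij = t.counts / n
    pi = t.row_sums / n
    pj = t.col_sums / n
    outer = pi[:, None] * pj[None, :]
    nz = pij > 0
    mutual_info = float(np.sum(pij[nz] * np.log(pij[nz] / outer[nz])))
    h1 = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    h2 = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    if h1 + h2 == 0.0:
        # both partitions are a single cluster: identical by construction
        return 1.0
    return 2.0 * mutual_info / (h1 + h2)
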