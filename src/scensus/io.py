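"""Expression-matrix and label-table input/output, CPM normalization, diagnostics.

The package keeps a single in-memory orientation — cells x genes — and
converts any on-disk orientation at read time.  Supported on-disk formats:

* MatrixMarket coordinate/array files (``.mtx``) with plain-text sidecar
  files ``<path>.rows`` and ``<path>.cols`` holding one identifier per line;
* delimited text (``.csv`` comma, anything else tab) with a header row and
  the identifier in the first column.

Label tables are two-column delimited files ``cell_id<sep>label``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "PartitionLabels",
    "read_expression",
    "write_expression",
    "cpm_normalize",
    "log_transform",
    "zero_fraction",
    "feature_matrix",
    "read_labels",
    "write_labels",
]

CPM_SCALE = 1_000_000.0


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """A cells x genes numeric matrix with identifiers and a layer tag.

    ``layer_tag`` records the processing state: raw ``counts``, per-cell
    counts-per-million ``cpm``, or natural-log transformed ``logcpm``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer_tag: str = "counts"

    _LAYERS = ("counts", "cpm", "logcpm")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"identifier lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        _check_unique(self.cell_ids, "cell_ids")
        _check_unique(self.gene_ids, "gene_ids")
        if self.layer_tag not in self._LAYERS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class PartitionLabels:
    """A hard partition of cells: one arbitrary hashable label per cell."""

    cell_ids: list[str]
    labels: list = field(default_factory=list)
    method_name: str = ""

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise ValueError(
                f"{len(self.cell_ids)} cells but {len(self.labels)} labels"
            )
        _check_unique(self.cell_ids, "cell_ids")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def as_codes(self) -> np.ndarray:
        """Integer codes 0..K-1 in order of first appearance."""
        seen: dict = {}
        codes = np.empty(len(self.labels), dtype=np.intp)
        for i, lab in enumerate(self.labels):
            codes[i] = seen.setdefault(lab, len(seen))
        return codes

    def reorder(self, cell_ids: Sequence[str]) -> "PartitionLabels":
        """Return a copy ordered to match ``cell_ids``; error on missing cells."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise ValueError(f"cells missing from partition: {missing[:10]}")
        return PartitionLabels(
            cell_ids=list(cell_ids),
            labels=[self.labels[index[c]] for c in cell_ids],
            method_name=self.method_name,
        )


def _read_sidecar(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing identifier sidecar file: {path}")
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(path: str, orientation: str = "cells_by_genes") -> ExpressionMatrix:
    """Read an expression matrix from disk into cells x genes orientation.

    Parameters
    ----------
    path
        ``.mtx`` (MatrixMarket, with ``<path>.rows``/``<path>.cols`` sidecars)
        or delimited text with a header row and row names in column one.
    orientation
        How the on-disk matrix is laid out; ``genes_by_cells`` input is
        transposed on read.
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".mtx"):
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        row_ids = _read_sidecar(path + ".rows")
        col_ids = _read_sidecar(path + ".cols")
        if len(row_ids) != values.shape[0] or len(col_ids) != values.shape[1]:
            raise ValueError(
                f"sidecar lengths ({len(row_ids)}, {len(col_ids)}) do not match "
                f"matrix shape {values.shape} in {path}"
            )
    else:
        sep = "," if path.endswith(".csv") else "\t"
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # surface the offending file/line
            raise ValueError(f"malformed expression file {path}: {exc}") from exc
        values = frame.to_numpy(dtype=float)
        row_ids = [str(i) for i in frame.index]
        col_ids = [str(c) for c in frame.columns]
    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values=values, cell_ids=row_ids, gene_ids=col_ids)


def write_expression(x: ExpressionMatrix, path: str) -> None:
    """Write cells x genes to ``.mtx`` (+ sidecars) or delimited text."""
    if path.endswith(".mtx"):
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(x.values))
        with open(path + ".rows", "w") as fh:
            fh.write("\n".join(x.cell_ids) + "\n")
        with open(path + ".cols", "w") as fh:
            fh.write("\n".join(x.gene_ids) + "\n")
    else:
        sep = "," if path.endswith(".csv") else "\t"
        pd.DataFrame(x.values, index=x.cell_ids, columns=x.gene_ids).to_csv(
            path, sep=sep
        )


def cpm_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: divide each cell by its total count, times 1e6."""
    if x.layer_tag != "counts":
        raise ValueError(f"cpm_normalize expects counts, got {x.layer_tag!r}")
    totals = x.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [x.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total count: {names}")
    values = x.values / totals[:, None] * CPM_SCALE
    return replace(x, values=values, layer_tag="cpm")


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural log1p of CPM values."""
    if x.layer_tag != "cpm":
        raise ValueError(f"log_transform expects cpm, got {x.layer_tag!r}")
    return replace(x, values=np.log1p(x.values), layer_tag="logcpm")


def zero_fraction(x: ExpressionMatrix) -> float:
    """Fraction of exactly-zero entries; dropout diagnostic."""
    if x.values.size == 0:
        raise ValueError("zero_fraction of an empty matrix is undefined")
    return float(np.count_nonzero(x.values == 0) / x.values.size)


def feature_matrix(
    x: ExpressionMatrix, use_pca: bool = False, n_components: int = 20
) -> np.ndarray:
    """The feature space used for neighbor graphs and cluster-quality scores.

    Raw counts are taken to log1p(CPM); matrices already tagged ``cpm`` or
    ``logcpm`` are advanced from their current state.  Optionally reduced to
    the top principal components (off by default).
    """
    if x.layer_tag == "counts":
        x = log_transform(cpm_normalize(x))
    elif x.layer_tag == "cpm":
        x = log_transform(x)
    feats = x.values
    if use_pca:
        n_components = min(n_components, min(feats.shape) - 1)
        centered = feats - feats.mean(axis=0)
        # deterministic full SVD; fixtures are small
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        feats = centered @ vt[:n_components].T
    return feats


def read_labels(
    path: str,
    method_name: str | None = None,
    header: bool = True,
    reference_cell_ids: Sequence[str] | None = None,
) -> PartitionLabels:
    """Read a two-column (cell_id, label) delimited file.

    With ``reference_cell_ids`` the partition is reordered to that list and
    missing cells raise an error naming them.  Labels are kept verbatim as
    strings; no numeric coercion.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = "," if path.endswith(".csv") else "\t"
    frame = pd.read_csv(
        path, sep=sep, header=0 if header else None, dtype=str, keep_default_na=False
    )
    if frame.shape[1] != 2:
        raise ValueError(f"label file {path} must have exactly 2 columns")
    name = method_name
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    p = PartitionLabels(
        cell_ids=list(frame.iloc[:, 0]),
        labels=list(frame.iloc[:, 1]),
        method_name=name,
    )
    if reference_cell_ids is not None:
        p = p.reorder(reference_cell_ids)
    return p


def write_labels(p: PartitionLabels, path: str, header: bool = True) -> None:
    sep = "," if path.endswith(".csv") else "\t"
    frame = pd.DataFrame({"cell_id": p.cell_ids, "label": p.labels})
    frame.to_csv(path, sep=sep, index=False, header=header)
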