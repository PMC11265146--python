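"""Expression-matrix and label I/O, plus feature alignment.

The canonical in-memory orientation is samples x genes: row *i* is a
biological sample, column *j* a gene, values on the log2 scale.  Files on
disk may be stored either way (public repositories differ), so the readers
and writers take an ``orientation`` flag and transpose as needed.

Missing values are permitted only upstream of k-nearest-neighbour
imputation; every downstream operation rejects them explicitly.  On disk a
missing cell is the sentinel token ``NA``; any non-numeric cell is read back
as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "read_expression",
    "write_expression",
    "align_features",
    "read_labels",
    "write_labels",
]

MISSING_SENTINEL = "NA"

_ORIENTATIONS = ("samples_in_rows", "genes_in_rows")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """A samples x genes grid of (log2-scale) expression values.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_samples, p_genes)``.  ``NaN`` marks a
        flagged-missing cell.
    sample_ids, gene_ids
        Ordered, unique identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if np.isinf(self.values).any():
            raise ValueError("values must be finite (NaN marks missing)")

    # -- shape conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def require_complete(self, op: str = "this operation") -> None:
        if self.has_missing:
            raise ValueError(f"{op} requires a matrix without missing values; run knn_impute first")

    # -- conversions --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    # -- subsetting ---------------------------------------------------------
    def subset_samples(self, idx: Iterable[int] | np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return ExpressionMatrix(self.values[idx], [self.sample_ids[i] for i in idx], list(self.gene_ids))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [pos[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(self.sample_ids), [str(g) for g in genes])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.sample_ids), list(self.gene_ids))

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class LabelVector:
    """Categorical class label per sample, aligned to an ExpressionMatrix."""

    sample_ids: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels must have equal length")
        _check_unique(self.sample_ids, "sample")
        if len(set(self.labels)) < 2:
            raise ValueError("≥2 classes required")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def subset(self, idx: Iterable[int]) -> "LabelVector":
        idx = list(idx)
        return LabelVector([self.sample_ids[i] for i in idx], [self.labels[i] for i in idx])

    def align_to(self, matrix: ExpressionMatrix) -> "LabelVector":
        """Reorder to the matrix's sample order; error on mismatch."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in matrix.sample_ids if s not in pos]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        return self.subset([pos[s] for s in matrix.sample_ids])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _check_rectangular(path, delimiter: str) -> None:
    width = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n = line.rstrip("\n").count(delimiter)
            if width is None:
                width = n
            elif n != width:
                raise ValueError(f"ragged row at line {lineno}: expected {width + 1} fields, found {n + 1}")


def read_expression(
    path,
    orientation: str = "samples_in_rows",
    delimiter: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression table into canonical samples x genes form.

    The first column holds row identifiers and the first row column
    identifiers.  Non-numeric cells (including the ``NA`` sentinel) become
    flagged-missing values.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    _check_rectangular(path, delimiter)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    _check_unique(header, "gene" if orientation == "samples_in_rows" else "sample")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    frame.columns = header  # undo pandas' mangling of duplicate names

    def _cell(s):  # float() is correctly rounded; pandas' fast parser is not
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    values = frame.map(_cell)
    if orientation == "genes_in_rows":
        values = values.T
    _check_unique(list(values.index), "sample")
    _check_unique(list(values.columns), "gene")
    return ExpressionMatrix.from_frame(values)


def write_expression(
    X: ExpressionMatrix,
    path,
    orientation: str = "samples_in_rows",
    delimiter: str = "\t",
) -> None:
    """Write a matrix as delimited text; lossless round-trip with read_expression."""
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    frame = X.to_frame()
    if orientation == "genes_in_rows":
        frame = frame.T
    # repr-based float formatting round-trips IEEE doubles exactly
    frame.to_csv(path, sep=delimiter, na_rep=MISSING_SENTINEL)


def align_features(X: ExpressionMatrix, Y: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, in X's gene order.

    Sample sets are untouched.  Raises if the intersection is empty.
    """
    in_y = set(Y.gene_ids)
    common = [g for g in X.gene_ids if g in in_y]
    if not common:
        raise ValueError("no genes in common between the two matrices")
    return X.subset_genes(common), Y.subset_genes(common)


def read_labels(path, delimiter: str = "\t") -> LabelVector:
    """Read a two-column (sample_id, label) table, preserving file order."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    if frame.shape[1] != 2:
        raise ValueError(f"expected a two-column table, found {frame.shape[1]} columns")
    return LabelVector(list(frame.iloc[:, 0]), list(frame.iloc[:, 1]))


def write_labels(labels: LabelVector, path, delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep=delimiter, index=False
    )
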