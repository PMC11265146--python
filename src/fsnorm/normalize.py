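"""Per-gene cross-platform normalization and preprocessing.

Two feature-specific normalizers map a *test* expression matrix onto a
*target* (training) distribution, gene by gene:

* **FSQN** (feature-specific quantile normalization) replaces each test
  gene's values with the target gene's empirical quantiles, so the test
  column's distribution matches the target column's exactly (equal sample
  counts) or up to linear interpolation (unequal counts).  Within-gene rank
  order of the test samples is preserved.

* **FSMVN** (feature-specific mean-variance normalization) standardizes
  each test gene to mean 0 / SD 1 and rescales it to the target gene's
  sample mean and standard deviation:

      x_norm = (x - mean(x)) / sd(x) * sd(y) + mean(y)

Both see only the target matrix, never test-fold labels, mirroring how a
training distribution is used in supervised learning.

Preprocessing helpers cover the usual upstream steps: log2(count + 1)
transformation, removal of genes with low mean expression, and k-nearest-
neighbour imputation of missing cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .io import ExpressionMatrix

__all__ = [
    "NormalizationResult",
    "log2_transform",
    "filter_low_expression",
    "knn_impute",
    "fsqn",
    "fsmvn",
]


@dataclass
class NormalizationResult:
    """Outcome of a normalization, with a per-gene audit of the target."""

    normalized: ExpressionMatrix
    method: str  # {log2_only, fsqn, fsmvn}
    target_summary: pd.DataFrame  # per-gene 'mean' and 'sd' of the target


def log2_transform(counts: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(count + offset); counts must be non-negative."""
    vals = counts.values
    if np.nanmin(vals) < 0:
        raise ValueError("counts must be non-negative")
    return ExpressionMatrix(np.log2(vals + offset), list(counts.sample_ids), list(counts.gene_ids))


def filter_low_expression(X: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose mean log2 expression is at least ``threshold``."""
    X.require_complete("filter_low_expression")
    keep = X.values.mean(axis=0) >= threshold
    if not keep.any():
        raise ValueError(f"all genes fall below the mean-expression threshold {threshold}")
    genes = [g for g, k in zip(X.gene_ids, keep) if k]
    return X.subset_genes(genes)


def knn_impute(X: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells with the mean of the k nearest samples' values.

    Distances are Euclidean over mutually observed genes.  Observed cells
    are returned unchanged; with no missing cells the matrix is returned
    as-is (a copy).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    vals = X.values
    miss = np.isnan(vals)
    if not miss.any():
        return X.copy()
    if miss.all(axis=1).any():
        bad = [s for s, m in zip(X.sample_ids, miss.all(axis=1)) if m]
        raise ValueError(f"samples with no observed values cannot be imputed: {bad}")
    observed_per_gene = (~miss).sum(axis=0)
    if (observed_per_gene < k).any():
        bad = [g for g, n in zip(X.gene_ids, observed_per_gene) if n < k]
        raise ValueError(f"genes with fewer than k={k} observed values: {bad[:5]}")
    frac = miss.mean()
    if frac > 0.20:
        warnings.warn(f"{frac:.1%} of cells are missing; kNN imputation may be unreliable")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(vals)
    out = vals.copy()
    out[miss] = filled[miss]
    return ExpressionMatrix(out, list(X.sample_ids), list(X.gene_ids))


def _check_pair(test: ExpressionMatrix, target: ExpressionMatrix, op: str) -> None:
    if test.gene_ids != target.gene_ids:
        raise ValueError(f"{op} requires identical gene features in identical order; run align_features first")
    test.require_complete(op)
    target.require_complete(op)


def _target_summary(target: ExpressionMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {"mean": target.values.mean(axis=0), "sd": target.values.std(axis=0, ddof=1)},
        index=target.gene_ids,
    )


def fsqn(test: ExpressionMatrix, target: ExpressionMatrix) -> NormalizationResult:
    """Feature-specific quantile normalization of ``test`` onto ``target``.

    With equal sample counts the i-th order statistic of each test column
    becomes the i-th order statistic of the target column.  With unequal
    counts the sorted target values are linearly interpolated at the test
    column's plotting positions (i-1)/(n-1) (the type-7 quantile
    convention).  Tied test values receive the mean of the values their
    positions would map to, so ties stay tied.
    """
    _check_pair(test, target, "fsqn")
    if target.n_samples < 2:
        raise ValueError("fsqn requires a target with at least 2 samples")
    X = test.values
    Y = target.values
    n, p = X.shape
    m = Y.shape[0]

    Y_sorted = np.sort(Y, axis=0)
    if n == m:
        # equal counts: the i-th order statistic maps exactly, no interpolation
        mapped = Y_sorted
    else:
        if n == 1:
            positions = np.array([0.5])
        else:
            positions = np.arange(n) / (n - 1)
        # type-7 interpolation of the sorted target at the plotting positions
        h = positions * (m - 1)
        lo = np.floor(h).astype(int)
        hi = np.minimum(lo + 1, m - 1)
        frac = (h - lo)[:, None]
        mapped = Y_sorted[lo, :] * (1.0 - frac) + Y_sorted[hi, :] * frac  # n x p

    out = np.empty_like(X)
    n_constant = 0
    for j in range(p):
        col = X[:, j]
        if np.all(col == col[0]):
            out[:, j] = np.median(Y[:, j])
            n_constant += 1
            continue
        order = np.argsort(col, kind="stable")
        col_sorted = col[order]
        vals = mapped[:, j].copy()
        # average mapped values over runs of tied test values
        if n > 1 and np.any(col_sorted[1:] == col_sorted[:-1]):
            starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
            sums = np.add.reduceat(vals, starts)
            counts = np.diff(np.r_[starts, n])
            means = sums / counts
            vals = np.repeat(means, counts)
        out[order, j] = vals
    if n_constant:
        warnings.warn(f"{n_constant} constant test gene(s) mapped to the target column median")

    normalized = ExpressionMatrix(out, list(test.sample_ids), list(test.gene_ids))
    return NormalizationResult(normalized, "fsqn", _target_summary(target))


def fsmvn(test: ExpressionMatrix, target: ExpressionMatrix) -> NormalizationResult:
    """Feature-specific mean-variance normalization of ``test`` onto ``target``.

    Each test column is standardized (sample SD, denominator n-1) and
    rescaled to the target column's mean and SD, so the output column's
    mean and SD equal the target's exactly.  A zero-variance test column
    maps to the target column mean (with a warning).
    """
    _check_pair(test, target, "fsmvn")
    if test.n_samples < 2:
        raise ValueError("fsmvn requires at least 2 test samples (sample SD undefined)")
    if target.n_samples < 2:
        raise ValueError("fsmvn requires a target with at least 2 samples")
    X = test.values
    Y = target.values

    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0, ddof=1)
    mu_y = Y.mean(axis=0)
    sd_y = Y.std(axis=0, ddof=1)

    degenerate = sd_x == 0.0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance test gene(s) mapped to the target column mean")
    if (sd_y == 0.0).any():
        warnings.warn(f"{int((sd_y == 0).sum())} zero-variance target gene(s); output is the constant target value")

    safe_sd = np.where(degenerate, 1.0, sd_x)
    out = (X - mu_x) / safe_sd * sd_y + mu_y
    out[:, degenerate] = mu_y[degenerate]

    normalized = ExpressionMatrix(out, list(test.sample_ids), list(test.gene_ids))
    return NormalizationResult(normalized, "fsmvn", _target_summary(target))
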