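"""Batch-effect diagnostics: SVD-based PCA and distribution overlap.

Platform (batch) effects show up as separation of the two platforms' samples
on the leading principal components and as divergent pooled value
distributions.  ``platform_mixing_score`` turns the PCA picture into a
number (silhouette of the platform labels on PC1-2: near 1 = separated,
near 0 or below = mixed); ``density_overlap`` measures the overlap
coefficient of the pooled-value densities of two matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix

__all__ = ["PCAResult", "pca_svd", "platform_mixing_score", "density_overlap"]


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components (U * S)
    loadings: np.ndarray  # genes x components (columns of V)
    variance_explained: np.ndarray  # fraction per component, sums ≤ 1
    sample_ids: list[str]


def pca_svd(
    X: ExpressionMatrix,
    n_components: int = 2,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA by singular value decomposition of the (centered) matrix."""
    X.require_complete("pca_svd")
    if n_components > min(X.n_samples - 1, X.n_genes):
        raise ValueError("n_components exceeds min(n_samples - 1, n_genes)")
    M = X.values.astype(float)
    if center:
        M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot unit-scale constant gene columns")
        M = M / sd
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        raise ValueError("constant matrix has no principal components")
    k = n_components
    return PCAResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        variance_explained=s[:k] ** 2 / total,
        sample_ids=list(X.sample_ids),
    )


def platform_mixing_score(scores: np.ndarray, platform) -> float:
    """Mean silhouette width of platform labels on the first two PC scores.

    Near 0 or negative: platforms mixed (no batch effect visible); near 1:
    platforms separated.
    """
    scores = np.asarray(scores, dtype=float)
    platform = np.asarray(platform)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must have at least two components")
    labels, counts = np.unique(platform, return_counts=True)
    if len(labels) != 2:
        raise ValueError("exactly two platform labels required")
    if counts.min() < 2:
        raise ValueError("each platform needs ≥2 samples (silhouette undefined)")
    return float(silhouette_score(scores[:, :2], platform))


def density_overlap(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    grid_size: int = 512,
    max_points: int = 100_000,
) -> float:
    """Overlap coefficient of the pooled-value densities of two matrices.

    Gaussian KDEs (Silverman bandwidth) of all values of each matrix are
    evaluated on a shared grid spanning the pooled range padded by three
    bandwidths; the integral of the pointwise minimum lies in [0, 1].
    Large matrices are deterministically strided down to ``max_points``
    values per side.
    """
    x = _flat(X, max_points)
    y = _flat(Y, max_points)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("density_overlap is undefined for constant input")
    kde_x = gaussian_kde(x, bw_method="silverman")
    kde_y = gaussian_kde(y, bw_method="silverman")
    h = max(kde_x.factor * x.std(ddof=1), kde_y.factor * y.std(ddof=1))
    lo = min(x.min(), y.min()) - 3 * h
    hi = max(x.max(), y.max()) + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    fx = kde_x(grid)
    fy = kde_y(grid)
    return float(np.trapezoid(np.minimum(fx, fy), grid))


def _flat(X: ExpressionMatrix, max_points: int) -> np.ndarray:
    X.require_complete("density_overlap")
    v = X.values.ravel()
    if len(v) > max_points:
        step = int(np.ceil(len(v) / max_points))
        v = v[::step]
    return v
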