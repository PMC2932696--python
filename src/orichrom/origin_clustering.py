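"""K-means clustering of origins by their occupancy pattern.

Origins are clustered on the ~800-bp region (−372 to +424 bp) that on
average contains the two nucleosomes surrounding the ACS.  NA cells are
imputed with the positional mean for the distance computation only;
sub-cluster mean profiles are computed from the raw (non-imputed) values.
Cluster labels are arbitrary — evaluations must compare partitions, not
raw labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .acs_alignment import AlignedMatrix
from .sequence_features import _pearson

__all__ = [
    "ClusterResult",
    "cluster_origins",
    "intergroup_correlations",
    "pairwise_profile_correlations",
]


@dataclass
class ClusterResult:
    k: int
    origin_ids: list[str]
    assignments: np.ndarray  # cluster index per origin, 0..k-1
    mean_profiles: np.ndarray  # (k, m), raw per-position averages
    positions: np.ndarray
    correlations: np.ndarray  # (k, k) Pearson between mean profiles
    heatmap_order: np.ndarray
    inertia: float


def pairwise_profile_correlations(means: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between mean profiles (rows)."""
    k = means.shape[0]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = _pearson(means[i], means[j])
    return out


def cluster_origins(
    matrix: AlignedMatrix,
    region: tuple[int, int] = (-372, 424),
    k: int = 4,
    seed: int = 0,
    max_iter: int = 10000,
    n_init: int = 1,
) -> ClusterResult:
    """Seeded k-means partition of origins on the region's occupancy values."""
    mask = matrix.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region} lies outside the position grid")
    if not (1 <= k <= matrix.n_origins):
        raise ValueError(f"k={k} out of range for {matrix.n_origins} origins")
    raw = matrix.values[:, mask]
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(raw, axis=0)
    col_means = np.nan_to_num(col_means, nan=0.0)
    X = np.where(np.isfinite(raw), raw, col_means)
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, tol=0.0,
                random_state=seed).fit(X)
    assign = km.labels_
    with np.errstate(invalid="ignore"):
        means = np.vstack(
            [np.nanmean(raw[assign == g], axis=0) for g in range(k)]
        )
    corr = pairwise_profile_correlations(means)
    order = []
    for g in range(k):
        rows = np.flatnonzero(assign == g)
        c = np.array([_pearson(X[r], means[g]) for r in rows])
        order.extend(rows[np.argsort(-c)])
    return ClusterResult(
        k=k,
        origin_ids=list(matrix.origin_ids),
        assignments=assign,
        mean_profiles=means,
        positions=matrix.positions[mask],
        correlations=corr,
        heatmap_order=np.asarray(order, dtype=np.intp),
        inertia=float(km.inertia_),
    )


def intergroup_correlations(result: ClusterResult) -> tuple[np.ndarray, float]:
    """The inter-group correlation matrix and its maximum off-diagonal —
    the criterion used to judge whether sub-clusters are distinct."""
    corr = result.correlations
    if result.k < 2:
        raise ValueError("need k >= 2 for inter-group correlations")
    off = corr[~np.eye(result.k, dtype=bool)]
    return corr, float(np.nanmax(off))
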