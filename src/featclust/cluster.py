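"""Sample clustering on a selected gene subset.

Samples are the objects and genes the coordinates.  The workhorse is
agglomerative clustering with Ward's linkage on Euclidean distances, cut to
k groups; a Spearman-correlation distance (1 - |rho| between samples) and
k-means are available as the alternatives used for robustness checks.
Cluster labels are arbitrary — downstream comparisons must be
label-permutation invariant (ARI, minority-group size).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

__all__ = [
    "hierarchical_partition",
    "kmeans_partition",
    "ward_cut_from_condensed",
]


def _check(matrix: pd.DataFrame, k: int) -> None:
    if matrix.shape[0] < 1:
        raise ValueError("need at least one gene to cluster on")
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > matrix.shape[1]:
        raise ValueError(
            f"cannot cut {matrix.shape[1]} samples into {k} groups"
        )


def ward_cut_from_condensed(dvec: np.ndarray, k: int) -> np.ndarray:
    """Ward linkage on a condensed distance vector, cut to k flat clusters."""
    Z = linkage(dvec, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def hierarchical_partition(
    matrix, distance: str = "euclidean", k: int = 2
) -> pd.Series:
    """Ward hierarchical clustering of samples, cut to k groups.

    ``distance='euclidean'`` uses sample-sample Euclidean distances over the
    selected genes; ``'spearman_correlation'`` uses 1 - |rho| with rho the
    Spearman correlation between samples.  Ward on the correlation distance
    follows common practice even though Ward's derivation is Euclidean.
    """
    matrix = pd.DataFrame(matrix)
    _check(matrix, k)
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    if distance == "euclidean":
        Z = linkage(x, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif distance == "spearman_correlation":
        ranks = rankdata(x, axis=1)
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks)
        rho = np.nan_to_num(rho, nan=0.0)
        d = 1.0 - np.abs(rho)
        np.fill_diagonal(d, 0.0)
        labels = ward_cut_from_condensed(squareform(d, checks=False), k)
    else:
        raise ValueError(f"unknown distance: {distance!r}")
    return pd.Series(labels, index=matrix.columns, name="cluster")


def kmeans_partition(
    matrix, k: int = 2, seed: int = 0, restarts: int = 10
) -> pd.Series:
    """Best-inertia k-means partition of the samples over seeded restarts."""
    matrix = pd.DataFrame(matrix)
    _check(matrix, k)
    x = matrix.to_numpy(dtype=float).T
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x) + 1
    return pd.Series(labels, index=matrix.columns, name="cluster")
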