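"""Variance reduction scores: hard (VRS), weighted (wVRS) and fuzzy (mVRS).

A gene whose values split cleanly into two groups has a small within-group
sum of squares relative to its total sum of squares.  VRS = WSS/TSS for the
2-means split; wVRS replaces the raw sums by per-group averages so a tiny
outlier cluster cannot fake a good score; mVRS uses fuzzy 2-means
memberships (soft k-means) in place of the hard split.  All three are
scale and shift invariant and low values indicate an informative split.

The internal 2-means split is found exactly: in one dimension the optimal
2-means clustering is a contiguous split of the sorted values, so the best
of the n-1 sorted splits is the global optimum of the k-means objective.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "best_univariate_split",
    "variance_reduction",
    "score_mvrs",
    "split_scores",
    "mvrs_scores",
]


def _split_stats(sorted_x: np.ndarray):
    """WSS of every contiguous split of sorted rows (shape (P, n)).

    Returns (wss_a, wss_b) with shape (P, n-1); column c is the split with
    c+1 points in the lower cluster.
    """
    c1 = np.cumsum(sorted_x, axis=1)
    c2 = np.cumsum(sorted_x**2, axis=1)
    n = sorted_x.shape[1]
    k = np.arange(1, n)
    sum_a, sumsq_a = c1[:, :-1], c2[:, :-1]
    sum_b = c1[:, -1:] - sum_a
    sumsq_b = c2[:, -1:] - sumsq_a
    wss_a = sumsq_a - sum_a**2 / k
    wss_b = sumsq_b - sum_b**2 / (n - k)
    return np.maximum(wss_a, 0.0), np.maximum(wss_b, 0.0)


def best_univariate_split(values) -> np.ndarray:
    """Globally optimal 2-means split of a 1-D sample.

    Returns a boolean mask marking the lower cluster (True).  Ties in the
    objective are broken toward the smaller lower cluster, which makes the
    split deterministic.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to split")
    if np.ptp(x) == 0:
        raise ValueError("cannot split constant values into 2 clusters")
    order = np.argsort(x, kind="stable")
    xs = x[order][None, :]
    wss_a, wss_b = _split_stats(xs)
    cut = int(np.argmin((wss_a + wss_b)[0]))  # cut+1 points in lower cluster
    lower = np.zeros(x.size, dtype=bool)
    lower[order[: cut + 1]] = True
    return lower


def variance_reduction(values, variant: str = "vrs", partitioner=None) -> float:
    """VRS or wVRS of one gene's values under a 2-group split.

    VRS = WSS/TSS in [0, 1]; wVRS = 0.5*(WSS_A/n_A + WSS_B/n_B)/(TSS/n),
    nonnegative and equal to VRS for balanced splits.  The default
    partitioner is the exact 2-means split; a custom ``partitioner`` must
    return a boolean mask (or two-level label array) over the samples.
    Constant genes give NaN.
    """
    if variant not in ("vrs", "wvrs"):
        raise ValueError(f"unknown variant: {variant!r}")
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("variance reduction requires at least 4 values")
    tss = ((x - x.mean()) ** 2).sum()
    if tss == 0:
        return float("nan")
    if partitioner is None:
        in_a = best_univariate_split(x)
    else:
        part = np.asarray(partitioner(x))
        if part.dtype != bool:
            levels = np.unique(part)
            if levels.size == 1:
                # one group holding every point: WSS == TSS, so VRS = 1;
                # the weighted form needs two non-empty groups
                return 1.0 if variant == "vrs" else float("nan")
            if levels.size != 2:
                raise ValueError("partitioner must produce 2 groups")
            part = part == levels[0]
        in_a = part
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        return float("nan")
    a, b = x[in_a], x[~in_a]
    wss_a = ((a - a.mean()) ** 2).sum()
    wss_b = ((b - b.mean()) ** 2).sum()
    if variant == "vrs":
        return float((wss_a + wss_b) / tss)
    n = x.size
    return float(0.5 * (wss_a / n_a + wss_b / n_b) / (tss / n))


def split_scores(matrix: np.ndarray):
    """Vectorized VRS and wVRS over the rows of a genes x samples array.

    Uses the exact sorted-split 2-means optimum per gene; constant rows get
    NaN for both scores.
    """
    x = np.asarray(matrix, dtype=float)
    G, n = x.shape
    vrs = np.full(G, np.nan)
    wvrs = np.full(G, np.nan)
    tss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ok = tss > 0
    if not ok.any():
        return vrs, wvrs
    xs = np.sort(x[ok], axis=1)
    wss_a, wss_b = _split_stats(xs)
    cut = np.argmin(wss_a + wss_b, axis=1)
    rows = np.arange(xs.shape[0])
    wa = wss_a[rows, cut]
    wb = wss_b[rows, cut]
    n_a = cut + 1.0
    n_b = n - n_a
    vrs[ok] = (wa + wb) / tss[ok]
    wvrs[ok] = 0.5 * (wa / n_a + wb / n_b) / (tss[ok] / n)
    return vrs, wvrs


def _fcm_batch(
    x: np.ndarray,
    centers0: np.ndarray,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-10,
):
    """Fuzzy 2-means on each row of x (shape (P, n)); returns (u, centers).

    ``u`` has shape (P, n, 2) with rows summing to 1 over clusters.
    """
    x = np.asarray(x, dtype=float)
    P, n = x.shape
    c = np.asarray(centers0, dtype=float).copy()  # (P, 2)
    expo = 2.0 / (m - 1.0)
    u = np.empty((P, n, 2))
    for _ in range(max_iter):
        d2 = (x[:, :, None] - c[:, None, :]) ** 2  # (P, n, 2)
        zero = d2 <= 1e-300
        any_zero = zero.any(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)
            u = inv / inv.sum(axis=2, keepdims=True)
        # points coinciding with a center: full membership there
        if any_zero.any():
            hard = zero / np.maximum(zero.sum(axis=2, keepdims=True), 1)
            u = np.where(any_zero[:, :, None], hard, u)
        um = u**m
        new_c = (um * x[:, :, None]).sum(axis=1) / np.maximum(
            um.sum(axis=1), 1e-300
        )
        shift = np.abs(new_c - c).max()
        c = new_c
        if shift < tol:
            break
    return u, c


def mvrs_scores(matrix: np.ndarray, m: float = 2.0, seed: int = 0) -> np.ndarray:
    """Vectorized mVRS over rows: fuzzy WSS / TSS, low = informative.

    Centers are initialized from the exact 2-means split; coincident
    centers are restarted once with jitter, else the gene scores NaN.
    """
    x = np.asarray(matrix, dtype=float)
    G, n = x.shape
    out = np.full(G, np.nan)
    tss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ok = tss > 0
    if not ok.any():
        return out
    xs = x[ok]
    sorted_x = np.sort(xs, axis=1)
    wss_a, wss_b = _split_stats(sorted_x)
    cut = np.argmin(wss_a + wss_b, axis=1)
    rows = np.arange(xs.shape[0])
    k = cut + 1
    c1 = np.cumsum(sorted_x, axis=1)
    mean_a = c1[rows, cut] / k
    mean_b = (c1[:, -1] - c1[rows, cut]) / (n - k)
    centers = np.stack([mean_a, mean_b], axis=1)

    degenerate = np.abs(centers[:, 0] - centers[:, 1]) <= 1e-300
    if degenerate.any():
        rng = np.random.default_rng(seed)
        spread = xs.std(axis=1, ddof=0)
        jitter = 1e-6 * np.maximum(spread, 1e-12)
        centers[degenerate, 0] -= jitter[degenerate] * rng.uniform(
            0.5, 1.5, degenerate.sum()
        )
        centers[degenerate, 1] += jitter[degenerate]

    u, c = _fcm_batch(xs, centers, m=m)
    still_bad = np.abs(c[:, 0] - c[:, 1]) <= 1e-300
    d2 = (xs[:, :, None] - c[:, None, :]) ** 2
    j = ((u**m) * d2).sum(axis=(1, 2))
    score = j / tss[ok]
    score[still_bad] = np.nan
    out[ok] = score
    return out


def score_mvrs(values, m: float = 2.0, seed: int = 0) -> float:
    """mVRS of one gene: fuzzy-membership-weighted WSS over TSS."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("mVRS requires at least 4 values")
    return float(mvrs_scores(x[None, :], m=m, seed=seed)[0])
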