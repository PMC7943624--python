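"""Hartigan & Hartigan dip statistic and Monte-Carlo p-values.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex up to the mode, concave after; an atom at
the mode is allowed).  Large dips indicate multimodality.  The statistic is
computed with the classic iterative greatest-convex-minorant (GCM) /
least-concave-majorant (LCM) algorithm: within the current modal interval
the GCM and LCM of the empirical CDF are fitted, the interval is shrunk to
where they are furthest apart, and the deviations of the empirical CDF from
the two fits outside that core are accumulated into the dip.

P-values are calibrated by Monte Carlo against samples of the same size
drawn from the uniform distribution (the asymptotically least favorable
unimodal null); null tables are computed once per sample size with a fixed
internal seed and cached, so for fixed n the p-value is a monotone
(non-increasing) function of the statistic and induces the same gene
ranking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "dip_null_table"]

# Null-table cache: (n, n_draws, seed) -> sorted array of null dips.
_NULL_TABLES: dict[tuple[int, int, int], np.ndarray] = {}

# Fixed calibration seed so rankings are reproducible across processes.
_CALIBRATION_SEED = 21721


def dip_statistic(values) -> float:
    """Dip statistic of a 1-D sample (ties allowed).

    Always >= 1/(2n); equals 1/(2n) for samples an affine CDF fits exactly.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    return _dip(x)


def _dip(x: np.ndarray) -> float:
    """Dip of sorted finite data (port of the classic GCM/LCM algorithm)."""
    n = x.size
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    low, high = 0, n - 1
    dip = 1.0  # in units of counts; final statistic is dip / (2n)

    # mn[j]: previous touch point of the GCM ending at j (computed once for
    # the whole sample; restricting to [low, high] reuses these chains).
    mn = np.zeros(n, dtype=np.intp)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (
                (x[j] - x[mnj]) * (mnj - mnmnj)
                < (x[mnj] - x[mnmnj]) * (j - mnj)
            ):
                break
            mn[j] = mnmnj

    # mj[k]: next touch point of the LCM starting at k.
    mj = np.zeros(n, dtype=np.intp)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (
                (x[k] - x[mjk]) * (mjk - mjmjk)
                < (x[mjk] - x[mjmjk]) * (k - mjk)
            ):
                break
            mj[k] = mjmjk

    while True:
        # Change points of the GCM from high down to low.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        ig = l_gcm
        ix = l_gcm - 1  # 1-based counters as in the reference algorithm

        # Change points of the LCM from low up to high.
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)
        ih = l_lcm
        iv = 2

        # Largest distance between the GCM and the LCM on [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix - 1]
                lcmiv = lcm[iv - 1]
                if gcmix > lcmiv:
                    # Next knot comes from the LCM: deviation of the LCM
                    # point from the GCM segment through it.
                    gcmi1 = gcm[ix]
                    dx = (lcmiv - gcmi1 + 1) - (
                        (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1)
                        / (x[gcmix] - x[gcmi1])
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # Next knot comes from the GCM.
                    lcmiv1 = lcm[iv - 2]
                    dx = (
                        (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1)
                        / (x[lcmiv] - x[lcmiv1])
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix - 1] == lcm[iv - 1]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # Deviation of the empirical CDF below the GCM on [low, gcm[ig]].
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb = gcm[j]      # lower index of the segment
            je = gcm[j - 1]  # upper index
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > dip_l:
                        dip_l = t

        # Deviation of the empirical CDF above the LCM on [lcm[ih], high].
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb = lcm[j - 1]
            je = lcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > dip_u:
                        dip_u = t

        dipnew = max(dip_l, dip_u)
        if dipnew > dip:
            dip = dipnew
        new_low = gcm[ig - 1]
        new_high = lcm[ih - 1]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


def dip_null_table(
    n: int,
    n_draws: int = 10_000,
    seed: int = _CALIBRATION_SEED,
) -> np.ndarray:
    """Sorted dip statistics of ``n_draws`` uniform null samples of size n.

    Cached per (n, n_draws, seed); the same table backs every p-value at a
    given sample size so rankings by p and by statistic coincide.
    """
    key = (int(n), int(n_draws), int(seed))
    table = _NULL_TABLES.get(key)
    if table is None:
        rng = np.random.default_rng(seed)
        draws = np.sort(rng.random((n_draws, n)), axis=1)
        table = np.sort([_dip(row) for row in draws])
        _NULL_TABLES[key] = table
    return table


def dip_pvalue(
    values,
    n_draws: int = 10_000,
    seed: int = _CALIBRATION_SEED,
) -> float:
    """Monte-Carlo p-value of the dip test of unimodality.

    p = (1 + #{null dips >= observed}) / (n_draws + 1) against the uniform
    null at the same sample size.  Requires n >= 4.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("dip p-value requires at least 4 observations")
    d = dip_statistic(x)
    table = dip_null_table(x.size, n_draws=n_draws, seed=seed)
    n_ge = table.size - np.searchsorted(table, d, side="left")
    return float((1 + n_ge) / (table.size + 1))
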