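"""Independent straight-from-formula reference implementations.

Everything here is deliberately written the slow, obvious way (scalar
loops, exhaustive enumeration, linear programming) and shares no code with
the package, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.optimize import linprog
from scipy.stats import spearmanr


# ---------------------------------------------------------------- location

def mean_oracle(x):
    return math.fsum(x) / len(x)


def quantile_type7(x, q):
    """Linear-interpolation (type-7) sample quantile, by hand."""
    xs = sorted(x)
    pos = (len(xs) - 1) * q
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def sd_oracle(x):
    m = mean_oracle(x)
    return math.sqrt(math.fsum((v - m) ** 2 for v in x) / (len(x) - 1))


def iqr_oracle(x):
    return quantile_type7(x, 0.75) - quantile_type7(x, 0.25)


# ---------------------------------------------------------------- entropy

def entropy_oracle(x):
    """Rectangular-kernel quadratic Renyi entropy, double loop."""
    n = len(x)
    h = 1.06 * sd_oracle(x) * n ** (-0.2)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            u = abs(x[i] - x[j]) / h
            total += 0.5 if u <= 1.0 else 0.0
    return -math.log(2.0 / (n * (n - 1) * h) * total)


# ----------------------------------------------------------- co-expression

def coexpression_oracle(matrix):
    """CoEx1/CoEx2 via pairwise scipy.stats.spearmanr."""
    g = matrix.shape[0]
    s = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            rho = spearmanr(matrix[i], matrix[j]).statistic
            s[i, j] = s[j, i] = abs(rho)
    coex1 = np.array([np.median(np.delete(s[i], i)) for i in range(g)])
    coex2 = np.array([np.sum(np.delete(s[i], i) ** 3) for i in range(g)])
    return coex1, coex2


# -------------------------------------------------------------------- dip

def dip_lp_oracle(sample):
    """Exact dip via LP over candidate modes (small n only).

    Minimizes eps such that a unimodal CDF (convex to the mode, concave
    after, atom allowed at the mode) stays within eps of the empirical CDF
    in sup norm.  The CDF is piecewise linear with knots at the unique data
    values; a mode strictly inside a gap reduces to a mode at an adjacent
    knot, so knot modes with an atom are exhaustive.
    """
    x = np.sort(np.asarray(sample, float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    m = u.size
    F = np.cumsum(counts) / n
    Fm = F - counts / n
    best = np.inf

    def solve(mode):
        nv = m + 2  # g_0..g_{m-1}, gL (left limit at the mode), eps
        ie = nv - 1
        igl = m
        A, b = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for i, c in coefs:
                row[i] += c
            A.append(row)
            b.append(rhs)

        for k in range(m):
            left = igl if k == mode else k
            le([(k, 1.0), (ie, -1.0)], F[k])
            le([(k, -1.0), (ie, -1.0)], -F[k])
            le([(left, 1.0), (ie, -1.0)], Fm[k])
            le([(left, -1.0), (ie, -1.0)], -Fm[k])
        for k in range(m - 1):
            le([(k, 1.0), (k + 1, -1.0)], 0.0)
        le([(igl, 1.0), (mode, -1.0)], 0.0)
        if mode > 0:
            le([(mode - 1, 1.0), (igl, -1.0)], 0.0)

        def chain(points, concave):
            for (xa, ia), (xb, ib), (xc, ic) in zip(
                points, points[1:], points[2:]
            ):
                coefs = [
                    (ib, (xc - xb) + (xb - xa)),
                    (ia, -(xc - xb)),
                    (ic, -(xb - xa)),
                ]
                if concave:
                    coefs = [(i, -c) for i, c in coefs]
                le(coefs, 0.0)

        chain([(u[k], k) for k in range(mode)] + [(u[mode], igl)], False)
        chain([(u[k], k) for k in range(mode, m)], True)

        c = np.zeros(nv)
        c[ie] = 1.0
        res = linprog(
            c, A_ub=np.array(A), b_ub=np.array(b),
            bounds=[(0, 1)] * nv, method="highs",
        )
        return res.fun if res.status == 0 else np.inf

    for t in range(m):
        best = min(best, solve(t))
    return best


# ---------------------------------------------------------------- mixture

def em_oracle(x, p, mu_a, mu_b, sigma, max_iter=1000, tol=1e-8,
              sigma_floor_frac=1e-6):
    """Scalar-loop EM for the equal-variance two-component normal mixture."""
    x = [float(v) for v in x]
    n = len(x)
    floor = sigma_floor_frac * math.sqrt(
        math.fsum((v - mean_oracle(x)) ** 2 for v in x) / n
    )
    p = min(max(p, 1e-10), 1 - 1e-10)
    sigma = max(sigma, floor)
    loglik = -math.inf
    converged = False

    def logphi(v, mu, sg):
        return -math.log(sg) - 0.5 * math.log(2 * math.pi) \
            - (v - mu) ** 2 / (2 * sg * sg)

    for _ in range(max_iter):
        la = [math.log(p) + logphi(v, mu_a, sigma) for v in x]
        lb = [math.log1p(-p) + logphi(v, mu_b, sigma) for v in x]
        lmix = [max(a, b) + math.log(math.exp(a - max(a, b))
                                     + math.exp(b - max(a, b)))
                for a, b in zip(la, lb)]
        ll = math.fsum(lmix)
        r = [math.exp(a - m) for a, m in zip(la, lmix)]
        ra = math.fsum(r)
        rb = n - ra
        mu_a = math.fsum(ri * v for ri, v in zip(r, x)) / max(ra, 1e-300)
        mu_b = math.fsum((1 - ri) * v for ri, v in zip(r, x)) / max(rb, 1e-300)
        var = math.fsum(
            ri * (v - mu_a) ** 2 + (1 - ri) * (v - mu_b) ** 2
            for ri, v in zip(r, x)
        ) / n
        sigma = max(math.sqrt(var), floor)
        p = min(max(ra / n, 1e-10), 1 - 1e-10)
        if abs(ll - loglik) / max(abs(ll), 1.0) < tol:
            loglik = ll
            converged = True
            break
        loglik = ll
    return {"p": p, "mu_a": mu_a, "mu_b": mu_b, "sigma": sigma,
            "loglik": loglik, "converged": converged}


def bi_oracle(x, starts):
    """BI via the scalar EM from explicit (p, mu_a, mu_b, sigma) starts."""
    best = None
    for st in starts:
        fit = em_oracle(x, *st)
        if best is None or fit["loglik"] > best["loglik"]:
            best = fit
    return best["p"] * (1 - best["p"]) * abs(best["mu_a"] - best["mu_b"]) \
        / best["sigma"]


# ---------------------------------------------------- variance reduction

def best_split_exhaustive(x):
    """Globally optimal 2-means split by enumerating all bipartitions."""
    n = len(x)
    best_wss, best_mask = math.inf, None
    for r in range(1, n):
        for combo in combinations(range(n), r):
            in_a = np.zeros(n, dtype=bool)
            in_a[list(combo)] = True
            a = [x[i] for i in range(n) if in_a[i]]
            b = [x[i] for i in range(n) if not in_a[i]]
            wss = (
                math.fsum((v - mean_oracle(a)) ** 2 for v in a)
                + math.fsum((v - mean_oracle(b)) ** 2 for v in b)
            )
            if wss < best_wss - 1e-15:
                best_wss, best_mask = wss, in_a
    return best_mask


def vrs_oracle(x, in_a):
    a = [x[i] for i in range(len(x)) if in_a[i]]
    b = [x[i] for i in range(len(x)) if not in_a[i]]
    m = mean_oracle(x)
    tss = math.fsum((v - m) ** 2 for v in x)
    wss = math.fsum((v - mean_oracle(a)) ** 2 for v in a) + \
        math.fsum((v - mean_oracle(b)) ** 2 for v in b)
    return wss / tss


def wvrs_oracle(x, in_a):
    a = [x[i] for i in range(len(x)) if in_a[i]]
    b = [x[i] for i in range(len(x)) if not in_a[i]]
    n, m = len(x), mean_oracle(x)
    tss = math.fsum((v - m) ** 2 for v in x)
    wss_a = math.fsum((v - mean_oracle(a)) ** 2 for v in a)
    wss_b = math.fsum((v - mean_oracle(b)) ** 2 for v in b)
    return 0.5 * (wss_a / len(a) + wss_b / len(b)) / (tss / n)


def mvrs_oracle(x, c0, c1, m=2.0, max_iter=300, tol=1e-10):
    """Scalar-loop fuzzy 2-means, objective over TSS."""
    x = [float(v) for v in x]
    n = len(x)
    centers = [c0, c1]
    u = [[0.0, 0.0] for _ in range(n)]
    for _ in range(max_iter):
        for i, v in enumerate(x):
            d2 = [(v - c) ** 2 for c in centers]
            if min(d2) <= 1e-300:
                zero = [1.0 if d <= 1e-300 else 0.0 for d in d2]
                tot = sum(zero)
                u[i] = [z / tot for z in zero]
            else:
                inv = [d ** (-1.0 / (m - 1.0)) for d in d2]
                tot = sum(inv)
                u[i] = [v2 / tot for v2 in inv]
        new_centers = []
        for c in range(2):
            num = math.fsum(u[i][c] ** m * x[i] for i in range(n))
            den = math.fsum(u[i][c] ** m for i in range(n))
            new_centers.append(num / max(den, 1e-300))
        shift = max(abs(a - b) for a, b in zip(centers, new_centers))
        centers = new_centers
        if shift < tol:
            break
    mu = mean_oracle(x)
    tss = math.fsum((v - mu) ** 2 for v in x)
    j = math.fsum(
        u[i][c] ** m * (x[i] - centers[c]) ** 2
        for i in range(n) for c in range(2)
    )
    return j / tss


# ------------------------------------------------------------------- BC

def bc_oracle(x):
    """Bimodality coefficient from bias-corrected sample moments, by hand."""
    n = len(x)
    m = mean_oracle(x)
    m2 = math.fsum((v - m) ** 2 for v in x) / n
    m3 = math.fsum((v - m) ** 3 for v in x) / n
    m4 = math.fsum((v - m) ** 4 for v in x) / n
    g1 = m3 / m2 ** 1.5
    skew = g1 * math.sqrt(n * (n - 1)) / (n - 2)
    g2 = m4 / m2 ** 2 - 3.0
    kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * g2 + 6.0)
    return (skew ** 2 + 1.0) / (kurt + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


# ------------------------------------------------------------------ ward

def ward_partition_oracle(x, k=2):
    """Brute-force Ward agglomeration of samples (rows of x); k groups.

    Merge cost is the ESS increase |A||B|/(|A|+|B|) * ||c_A - c_B||^2, a
    monotone transform of Ward linkage distances, so the merge order (and
    flat cut) matches a correct Ward implementation.
    """
    clusters = [[i] for i in range(x.shape[0])]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = x[clusters[i]], x[clusters[j]]
                ca, cb = a.mean(axis=0), b.mean(axis=0)
                cost = len(a) * len(b) / (len(a) + len(b)) * \
                    float(((ca - cb) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(x.shape[0], dtype=int)
    for c, members in enumerate(clusters):
        labels[members] = c + 1
    return labels


# ------------------------------------------------------------------- ARI

def ari_oracle(a, b):
    """ARI from the contingency table, textbook formula."""
    a = list(a)
    b = list(b)
    la, lb = sorted(set(a)), sorted(set(b))
    nij = np.zeros((len(la), len(lb)))
    for x, y in zip(a, b):
        nij[la.index(x), lb.index(y)] += 1

    def c2(v):
        return v * (v - 1) / 2.0

    sum_ij = sum(c2(v) for v in nij.ravel())
    sum_a = sum(c2(v) for v in nij.sum(axis=1))
    sum_b = sum(c2(v) for v in nij.sum(axis=0))
    n = len(a)
    expected = sum_a * sum_b / c2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return (sum_ij - expected) / (max_index - expected)


# ----------------------------------------------------------- hypergeometric

def fisher_greater_oracle(a, b, c, d):
    """One-sided Fisher p by direct hypergeometric tail summation."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def logc(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) \
            - math.lgamma(n_ - k_ + 1)

    denom = logc(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += math.exp(logc(row1, k) + logc(n - row1, col1 - k) - denom)
    return min(p, 1.0)
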