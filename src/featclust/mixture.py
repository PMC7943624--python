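"""Equal-variance two-component Gaussian mixtures and the bimodality index.

A gene's expression across samples is modelled as
f(x) = p*N(mu_A, sigma) + (1-p)*N(mu_B, sigma), fitted by EM.  The
bimodality index BI = p(1-p)*|mu_A - mu_B| / sigma rewards well-separated
components with a balanced mixing fraction.  Two initialization modes are
provided: a grid of 10 mixing fractions evenly spaced in (0, 1) (best
log-likelihood kept), and a cheap single start taken from a 2-means split
of the values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vrs import best_univariate_split

__all__ = ["MixtureFit", "fit_bimodal_mixture", "bimodality_index"]

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000
_SIGMA_FLOOR_FRAC = 1e-6  # times the data SD, prevents variance collapse


@dataclass(frozen=True)
class MixtureFit:
    """Fitted equal-variance two-component normal mixture."""

    p: float
    mu_a: float
    mu_b: float
    sigma: float
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly in (0, 1)")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def _em_batch(
    x: np.ndarray,
    p0: np.ndarray,
    mu_a0: np.ndarray,
    mu_b0: np.ndarray,
    sigma0: np.ndarray,
    max_iter: int = _EM_MAX_ITER,
    tol: float = _EM_TOL,
) -> dict[str, np.ndarray]:
    """EM for P independent problems at once (x has shape (P, n)).

    Stops per problem when the relative log-likelihood change drops below
    ``tol``; sigma is floored at ``_SIGMA_FLOOR_FRAC`` times each problem's
    data SD.
    """
    x = np.asarray(x, dtype=float)
    P, n = x.shape
    p = np.clip(np.asarray(p0, dtype=float).copy(), 1e-10, 1 - 1e-10)
    mu_a = np.asarray(mu_a0, dtype=float).copy()
    mu_b = np.asarray(mu_b0, dtype=float).copy()
    floor = _SIGMA_FLOOR_FRAC * x.std(axis=1, ddof=0)
    floor = np.where(floor > 0, floor, 1e-300)
    sigma = np.maximum(np.asarray(sigma0, dtype=float).copy(), floor)

    loglik = np.full(P, -np.inf)
    active = np.ones(P, dtype=bool)
    converged = np.zeros(P, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        xs = x[idx]
        pa = p[idx, None]
        inv2s2 = 1.0 / (2.0 * sigma[idx, None] ** 2)
        log_norm = -np.log(sigma[idx, None]) - 0.5 * np.log(2 * np.pi)
        la = np.log(pa) + log_norm - (xs - mu_a[idx, None]) ** 2 * inv2s2
        lb = np.log1p(-pa) + log_norm - (xs - mu_b[idx, None]) ** 2 * inv2s2
        m = np.maximum(la, lb)
        log_mix = m + np.log(np.exp(la - m) + np.exp(lb - m))
        ll = log_mix.sum(axis=1)

        r = np.exp(la - log_mix)  # responsibility of component A
        ra = r.sum(axis=1)
        rb = n - ra
        ra_safe = np.maximum(ra, 1e-300)
        rb_safe = np.maximum(rb, 1e-300)
        new_mu_a = (r * xs).sum(axis=1) / ra_safe
        new_mu_b = ((1 - r) * xs).sum(axis=1) / rb_safe
        var = (
            (r * (xs - new_mu_a[:, None]) ** 2).sum(axis=1)
            + ((1 - r) * (xs - new_mu_b[:, None]) ** 2).sum(axis=1)
        ) / n
        new_sigma = np.maximum(np.sqrt(var), floor[idx])
        new_p = np.clip(ra / n, 1e-10, 1 - 1e-10)

        rel = np.abs(ll - loglik[idx]) / np.maximum(np.abs(ll), 1.0)
        done = rel < tol

        p[idx] = new_p
        mu_a[idx] = new_mu_a
        mu_b[idx] = new_mu_b
        sigma[idx] = new_sigma
        loglik[idx] = ll
        converged[idx[done]] = True
        active[idx[done]] = False

    return {
        "p": p, "mu_a": mu_a, "mu_b": mu_b, "sigma": sigma,
        "loglik": loglik, "converged": converged,
    }


def _grid_starts(x: np.ndarray, n_starts: int = 10):
    """Quantile-split starts for mixing fractions k/(n_starts+1), k=1..n_starts."""
    xs = np.sort(x)
    n = xs.size
    starts = []
    for k in range(1, n_starts + 1):
        frac = k / (n_starts + 1.0)
        cut = min(max(int(round(frac * n)), 1), n - 1)
        lo, hi = xs[:cut], xs[cut:]
        var = (
            ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        ) / n
        starts.append((frac, lo.mean(), hi.mean(), np.sqrt(var)))
    return starts


def _kmeans_start(x: np.ndarray):
    lower = best_univariate_split(x)
    lo, hi = x[lower], x[~lower]
    var = (((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()) / x.size
    return (lo.size / x.size, lo.mean(), hi.mean(), np.sqrt(var))


def fit_bimodal_mixture(values, starts: str = "grid") -> MixtureFit:
    """Fit the equal-variance two-component mixture to one gene's values.

    ``starts='grid'`` runs EM from 10 starts with the mixing fraction evenly
    spaced in (0, 1) and keeps the best log-likelihood; ``'kmeans_single'``
    uses a single start derived from the optimal 2-means split (means,
    pooled SD, and size fraction).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("mixture fit requires at least 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("cannot fit a mixture to constant values")
    if starts == "grid":
        inits = _grid_starts(x)
    elif starts == "kmeans_single":
        inits = [_kmeans_start(x)]
    else:
        raise ValueError(f"unknown starts mode: {starts!r}")

    P = len(inits)
    res = _em_batch(
        np.broadcast_to(x, (P, x.size)),
        np.array([s[0] for s in inits]),
        np.array([s[1] for s in inits]),
        np.array([s[2] for s in inits]),
        np.array([s[3] for s in inits]),
    )
    best = int(np.argmax(res["loglik"]))
    return MixtureFit(
        p=float(res["p"][best]),
        mu_a=float(res["mu_a"][best]),
        mu_b=float(res["mu_b"][best]),
        sigma=float(res["sigma"][best]),
        loglik=float(res["loglik"][best]),
        converged=bool(res["converged"][best]),
    )


def bimodality_index(fit: MixtureFit, sqrt_fraction: bool = False) -> float:
    """BI = p(1-p)|mu_A - mu_B| / sigma.

    ``sqrt_fraction=True`` gives the originally published variant with
    sqrt(p(1-p)) in place of p(1-p).
    """
    frac = fit.p * (1.0 - fit.p)
    if sqrt_fraction:
        frac = np.sqrt(frac)
    return float(frac * abs(fit.mu_a - fit.mu_b) / fit.sigma)


def bimodality_index_scores(
    matrix: np.ndarray,
    starts: str = "grid",
    sqrt_fraction: bool = False,
) -> np.ndarray:
    """Vectorized BI over the rows of a genes x samples array.

    Degenerate (constant) rows get NaN.  All starts for all genes are run as
    one EM batch per start.
    """
    x = np.asarray(matrix, dtype=float)
    G, n = x.shape
    ok = np.ptp(x, axis=1) > 0
    out = np.full(G, np.nan)
    if not ok.any():
        return out
    xs = x[ok]

    if starts == "grid":
        sorted_x = np.sort(xs, axis=1)
        n_starts = 10
        best = None
        for k in range(1, n_starts + 1):
            frac = k / (n_starts + 1.0)
            cut = min(max(int(round(frac * n)), 1), n - 1)
            lo, hi = sorted_x[:, :cut], sorted_x[:, cut:]
            mu_a0 = lo.mean(axis=1)
            mu_b0 = hi.mean(axis=1)
            var0 = (
                ((lo - mu_a0[:, None]) ** 2).sum(axis=1)
                + ((hi - mu_b0[:, None]) ** 2).sum(axis=1)
            ) / n
            res = _em_batch(
                xs, np.full(xs.shape[0], frac), mu_a0, mu_b0, np.sqrt(var0)
            )
            if best is None:
                best = res
            else:
                improve = res["loglik"] > best["loglik"]
                for key in best:
                    best[key] = np.where(improve, res[key], best[key])
    elif starts == "kmeans_single":
        inits = np.array([_kmeans_start(row) for row in xs])
        best = _em_batch(xs, inits[:, 0], inits[:, 1], inits[:, 2], inits[:, 3])
    else:
        raise ValueError(f"unknown starts mode: {starts!r}")

    frac = best["p"] * (1.0 - best["p"])
    if sqrt_fraction:
        frac = np.sqrt(frac)
    out[ok] = frac * np.abs(best["mu_a"] - best["mu_b"]) / best["sigma"]
    return out
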