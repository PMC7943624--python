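"""Supervised control: per-gene negative-binomial GLM Wald tests.

Counts K_ij are modelled as NB(mean = s_j * q_ij, dispersion = alpha_i)
with log2 q_ij = beta_i0 + beta_i1 * x_j, where x_j encodes the two sample
groups and s_j are fixed size factors entering as offsets.  For each gene
the group coefficients are fitted by scoring iterations (closed-form for a
two-group design) and the gene-wise dispersion alpha_i by profile maximum
likelihood on a log grid — no empirical-Bayes shrinkage.  Genes are ranked
by the Wald p-value of H0: beta_i1 = 0.

Everything is vectorized across genes, so tens of thousands of fits take
seconds; statsmodels fits the identical model one gene at a time and serves
as the numerical reference in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["nb_wald_fit", "supervised_pvalues", "welch_pvalues"]

_ALPHA_MIN = 1e-8
_ALPHA_MAX = 50.0


def _solve_group_rate(y, s, alpha, t0, n_iter=50, tol=1e-12):
    """Solve sum_j (y_j - t*s_j) / (1 + alpha*t*s_j) = 0 for t, per gene.

    y, s broadcast to (G, m) for one group's samples; t is the group mean
    rate q_g (so mu_j = t*s_j).  The score is monotone decreasing in t, and
    Newton in log t converges fast from the moment start t0.
    """
    t = np.maximum(np.asarray(t0, dtype=float).copy(), 1e-8)
    for _ in range(n_iter):
        ts = t[:, None] * s
        denom = 1.0 + alpha[:, None] * ts
        f = ((y - ts) / denom).sum(axis=1)
        # df/dt = -sum s_j (1 + alpha y_j) / denom^2
        df = -(s * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = f / (df * t)  # Newton step in u = log t
        step = np.clip(step, -3.0, 3.0)
        t_new = t * np.exp(-step)
        t_new = np.clip(t_new, 1e-12, 1e12)
        if np.max(np.abs(np.log(t_new / t))) < tol:
            t = t_new
            break
        t = t_new
    return t


def _nb_loglik(y, mu, alpha):
    """NB2 log-likelihood summed over samples, per gene (all (G, n))."""
    inv = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    return (
        special.gammaln(y + inv[:, None])
        - special.gammaln(inv[:, None])
        - special.gammaln(y + 1.0)
        + y * np.log(alpha[:, None] * mu)
        - (y + inv[:, None]) * np.log1p(alpha[:, None] * mu)
    ).sum(axis=1)


def _profile_alpha(y, s, in_b, q_a, q_b, alpha, n_coarse=25, n_fine=15):
    """Per-gene ML dispersion on a log grid, given current group rates."""
    mu = np.where(in_b[None, :], q_b[:, None], q_a[:, None]) * s[None, :]
    grid = np.exp(np.linspace(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX), n_coarse))
    ll = np.stack([_nb_loglik(y, mu, np.full(y.shape[0], a)) for a in grid])
    best = np.argmax(ll, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, n_coarse - 1)]
    # refine within the bracketing interval
    f = np.linspace(0.0, 1.0, n_fine)
    fine = np.exp(
        np.log(lo)[None, :] + f[:, None] * (np.log(hi) - np.log(lo))[None, :]
    )
    llf = np.stack(
        [_nb_loglik(y, mu, fine[i]) for i in range(n_fine)]
    )
    bestf = np.argmax(llf, axis=0)
    return fine[bestf, np.arange(y.shape[0])]


def nb_wald_fit(
    counts: np.ndarray,
    in_group_b: np.ndarray,
    size_factors: np.ndarray,
    n_outer: int = 4,
) -> dict[str, np.ndarray]:
    """Fit the two-group NB GLM to every gene; return coefficients and p-values.

    ``counts``: (G, n) nonnegative integers; ``in_group_b``: boolean per
    sample; ``size_factors``: positive per sample.  Returns log2 fold
    change, Wald statistic/p-value, fitted dispersion, and a flag for genes
    where the moment fallback was used.  All-zero genes get p = 1.
    """
    y = np.asarray(counts, dtype=float)
    in_b = np.asarray(in_group_b, dtype=bool)
    s = np.asarray(size_factors, dtype=float)
    G, n = y.shape
    if in_b.size != n or s.size != n:
        raise ValueError("labels/size factors do not match the sample count")
    if not (in_b.any() and (~in_b).any()):
        raise ValueError("both label groups must be non-empty")
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")

    y_a, s_a = y[:, ~in_b], s[~in_b]
    y_b, s_b = y[:, in_b], s[in_b]
    nonzero = y.sum(axis=1) > 0

    # moment start for the dispersion, from normalized counts
    xn = y / s[None, :]
    m_ = xn.mean(axis=1)
    v_ = xn.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha0 = (v_ - m_) / m_**2
    alpha = np.clip(np.nan_to_num(alpha0, nan=_ALPHA_MIN), _ALPHA_MIN, _ALPHA_MAX)

    q_a = np.maximum(y_a.sum(axis=1) / s_a.sum(), 1e-8)
    q_b = np.maximum(y_b.sum(axis=1) / s_b.sum(), 1e-8)

    for _ in range(n_outer):
        q_a = _solve_group_rate(y_a, s_a[None, :], alpha, q_a)
        q_b = _solve_group_rate(y_b, s_b[None, :], alpha, q_b)
        alpha = _profile_alpha(y, s, in_b, q_a, q_b, alpha)

    # Wald test on b1 = log(q_b/q_a); expected information with weights
    # w_j = mu_j / (1 + alpha*mu_j) gives var(b1) = 1/sum_A w + 1/sum_B w.
    mu_a = q_a[:, None] * s_a[None, :]
    mu_b = q_b[:, None] * s_b[None, :]
    w_a = (mu_a / (1.0 + alpha[:, None] * mu_a)).sum(axis=1)
    w_b = (mu_b / (1.0 + alpha[:, None] * mu_b)).sum(axis=1)
    b1 = np.log(q_b / q_a)
    se = np.sqrt(1.0 / np.maximum(w_a, 1e-300) + 1.0 / np.maximum(w_b, 1e-300))
    z = b1 / se
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    pvalues[~nonzero] = 1.0

    return {
        "log2_fold_change": b1 / np.log(2.0),
        "wald_stat": z,
        "pvalue": pvalues,
        "dispersion": alpha,
        "all_zero": ~nonzero,
    }


def supervised_pvalues(counts, labels, s) -> "pd.Series":
    """Per-gene NB GLM Wald p-values for a two-group label (lower = better).

    ``counts`` is a genes x samples DataFrame of filtered raw counts (not
    variance-stabilized), ``labels`` a two-level per-sample label, ``s``
    size factors aligned with the samples.
    """
    counts = pd.DataFrame(counts)
    labels = pd.Series(labels).loc[counts.columns]
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("labels must have exactly two levels")
    in_b = (labels == levels[1]).to_numpy()
    sv = pd.Series(s).loc[counts.columns].to_numpy(dtype=float)
    res = nb_wald_fit(counts.to_numpy(dtype=float), in_b, sv)
    return pd.Series(res["pvalue"], index=counts.index, name="pval")


def welch_pvalues(matrix, labels) -> "pd.Series":
    """Welch two-sample t-test per gene for real-valued matrices.

    The supervised control for inputs that are not counts (a labelled
    deviation from the count-based NB test, used when no NB model applies).
    """
    matrix = pd.DataFrame(matrix)
    labels = pd.Series(labels).loc[matrix.columns]
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("labels must have exactly two levels")
    a = matrix.loc[:, (labels == levels[0]).to_numpy()].to_numpy()
    b = matrix.loc[:, (labels == levels[1]).to_numpy()].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=matrix.index, name="welch_pval")
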