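"""The thirteen unsupervised per-gene scores and the selection machinery.

Every method maps a genes x samples expression matrix to one score per gene
with a declared selection direction:

==========  ============================================  ==========
method      score                                         direction
==========  ============================================  ==========
m           mean across samples                           higher
q3          third quartile across samples                 higher
sd          sample standard deviation (n-1)               higher
iqr         interquartile range Q3 - Q1                   higher
ent         quadratic Renyi entropy (kernel estimator)    higher
coex1       median |Spearman| correlation to other genes  higher
coex2       sum of cubed |Spearman| correlations          higher
dip         dip-test Monte-Carlo p-value                  lower
bi          bimodality index of a 2-component mixture     higher
vrs         variance reduction score WSS/TSS              lower
wvrs        sample-size-weighted VRS                      lower
mvrs        fuzzy (soft 2-means) VRS                      lower
bc          bimodality coefficient from skew/kurtosis     higher
==========  ============================================  ==========

Degenerate genes (constant, or otherwise unscorable) receive NaN and are
never selectable: they rank after every scorable gene.  Quantiles use the
linear-interpolation (type-7) definition throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dip import dip_null_table, dip_statistic
from .mixture import bimodality_index_scores
from .vrs import mvrs_scores, split_scores

__all__ = [
    "EntropyConfig",
    "ScoreTable",
    "METHODS",
    "score_location",
    "score_spread",
    "score_entropy",
    "score_coexpression",
    "score_dip",
    "score_bimodality_index",
    "score_vrs",
    "score_bimodality_coefficient",
    "bimodality_coefficient",
    "score_matrix",
    "select_top",
    "random_selection",
]


@dataclass(frozen=True)
class EntropyConfig:
    """Rectangular-kernel entropy estimator settings.

    The bandwidth follows Silverman's rule h = 1.06 * sigma_hat * n^(-1/5).
    """

    bandwidth_factor: float = 1.06
    bandwidth_exponent: float = -0.2


@dataclass
class ScoreTable:
    """Per-gene scores for one method plus its selection direction.

    ``direction`` is "higher" (larger score = more informative) or "lower".
    ``tiebreak`` is an optional secondary score (always higher-is-better)
    used to order genes whose primary scores tie exactly — e.g. the dip
    statistic behind its Monte-Carlo p-value.
    """

    method: str
    scores: pd.Series
    direction: str
    tiebreak: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError("direction must be 'higher' or 'lower'")
        self.scores = pd.Series(self.scores)
        if self.tiebreak is not None:
            self.tiebreak = pd.Series(self.tiebreak).loc[self.scores.index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.scores.index

    def ranking(self) -> pd.Index:
        """All scorable genes, best first (NaN-scored genes excluded)."""
        s = self.scores
        ok = s.notna().to_numpy()
        primary = s.to_numpy(dtype=float)
        if self.direction == "higher":
            primary = -primary
        secondary = (
            -self.tiebreak.to_numpy(dtype=float)
            if self.tiebreak is not None
            else np.zeros(len(s))
        )
        position = np.arange(len(s))
        order = np.lexsort((position[ok], secondary[ok], primary[ok]))
        return s.index[np.flatnonzero(ok)[order]]


def select_top(scores: ScoreTable, k: int) -> pd.Index:
    """The k best genes per the method's direction, in rank order.

    NaN scores are excluded; exact ties are broken by the table's secondary
    score and then by input gene order, so selection is deterministic.
    """
    ranked = scores.ranking()
    if k > len(ranked):
        raise ValueError(
            f"method {scores.method!r}: requested top {k} genes but only "
            f"{len(ranked)} genes have scores"
        )
    return ranked[:k]


def random_selection(gene_ids, k: int, seed: int) -> pd.Index:
    """Uniform sample of k genes without replacement (negative control)."""
    ids = pd.Index(gene_ids)
    if k > len(ids):
        raise ValueError(f"cannot select {k} genes out of {len(ids)}")
    rng = np.random.default_rng(seed)
    return ids[rng.choice(len(ids), size=k, replace=False)]


def _as_array(matrix: pd.DataFrame) -> np.ndarray:
    return pd.DataFrame(matrix).to_numpy(dtype=float)


def score_location(matrix, stat: str = "mean") -> ScoreTable:
    """Per-gene mean (M) or third quartile (Q3); higher is better."""
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    if x.shape[1] < 1:
        raise ValueError("need at least 1 sample")
    if stat == "mean":
        values = x.mean(axis=1)
    elif stat == "q3":
        values = np.quantile(x, 0.75, axis=1)
    else:
        raise ValueError(f"unknown location stat: {stat!r}")
    name = "m" if stat == "mean" else "q3"
    return ScoreTable(name, pd.Series(values, index=matrix.index), "higher")


def score_spread(matrix, stat: str = "sd") -> ScoreTable:
    """Per-gene SD (n-1 denominator) or IQR; higher is better."""
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    if x.shape[1] < 2:
        raise ValueError("spread scores need at least 2 samples")
    if stat == "sd":
        values = x.std(axis=1, ddof=1)
    elif stat == "iqr":
        values = np.quantile(x, 0.75, axis=1) - np.quantile(x, 0.25, axis=1)
    else:
        raise ValueError(f"unknown spread stat: {stat!r}")
    return ScoreTable(stat, pd.Series(values, index=matrix.index), "higher")


def score_entropy(matrix, cfg: EntropyConfig = EntropyConfig()) -> ScoreTable:
    """Quadratic Renyi entropy via a pairwise rectangular-kernel U-statistic.

    ENT = -log( (2 / (n(n-1)h)) * sum_{i<j} K((x_i-x_j)/h) ) with
    K(u) = 1/2 * 1{|u| <= 1} and h = 1.06 * sigma_hat * n^(-1/5).  Constant
    genes (sigma_hat = 0) are degenerate and score NaN.
    """
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    G, n = x.shape
    if n < 2:
        raise ValueError("entropy scores need at least 2 samples")
    sd = x.std(axis=1, ddof=1)
    h = cfg.bandwidth_factor * sd * n**cfg.bandwidth_exponent
    values = np.full(G, np.nan)
    ok = h > 0
    chunk = max(1, int(2e7 // (n * n)))
    idx = np.flatnonzero(ok)
    iu = np.triu_indices(n, k=1)
    for start in range(0, idx.size, chunk):
        rows = idx[start : start + chunk]
        gaps = np.abs(x[rows, :, None] - x[rows, None, :])[:, iu[0], iu[1]]
        within = (gaps <= h[rows, None]).sum(axis=1)
        est = within / (n * (n - 1) * h[rows])  # = (2/(n(n-1)h)) * sum K
        with np.errstate(divide="ignore"):
            values[rows] = -np.log(est)
    return ScoreTable("ent", pd.Series(values, index=matrix.index), "higher")


def score_coexpression(matrix, variant: str = "coex1") -> ScoreTable:
    """Co-expression scores from the |Spearman| similarity matrix.

    s_ij = |Spearman rank correlation of genes i and j| (average ranks for
    ties).  CoEx1_i = median over j != i of s_ij; CoEx2_i = sum over j != i
    of s_ij^3.  Constant genes contribute 0 similarity to others and score
    NaN themselves.
    """
    if variant not in ("coex1", "coex2"):
        raise ValueError(f"unknown co-expression variant: {variant!r}")
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    G, n = x.shape
    if G < 2 or n < 3:
        raise ValueError("co-expression needs >= 2 genes and >= 3 samples")
    ranks = stats.rankdata(x, axis=1)
    constant = np.ptp(x, axis=1) == 0
    with np.errstate(invalid="ignore"):
        s = np.abs(np.corrcoef(ranks))
    s[constant, :] = 0.0
    s[:, constant] = 0.0
    np.fill_diagonal(s, np.nan)
    if variant == "coex1":
        values = np.nanmedian(s, axis=1)
    else:
        values = np.nansum(s**3, axis=1)
    values[constant] = np.nan
    name = "coex1" if variant == "coex1" else "coex2"
    return ScoreTable(name, pd.Series(values, index=matrix.index), "higher")


def score_dip(matrix, n_draws: int = 10_000) -> ScoreTable:
    """Dip-test selection: Monte-Carlo p-values, lower = more multimodal.

    The dip statistic itself is attached as the tiebreak, so for fixed n the
    induced ranking is exactly the ranking by descending dip statistic.
    """
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    G, n = x.shape
    if n < 4:
        raise ValueError("dip p-values need at least 4 samples")
    table = dip_null_table(n, n_draws=n_draws)
    dips = np.array([dip_statistic(row) for row in x])
    n_ge = table.size - np.searchsorted(table, dips, side="left")
    pvals = (1 + n_ge) / (table.size + 1)
    return ScoreTable(
        "dip",
        pd.Series(pvals, index=matrix.index),
        "lower",
        tiebreak=pd.Series(dips, index=matrix.index),
    )


def score_bimodality_index(
    matrix, starts: str = "grid", sqrt_fraction: bool = False
) -> ScoreTable:
    """Bimodality index per gene from the equal-variance mixture fit."""
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    if x.shape[1] < 10:
        raise ValueError("bimodality index needs at least 10 samples")
    values = bimodality_index_scores(x, starts=starts, sqrt_fraction=sqrt_fraction)
    return ScoreTable("bi", pd.Series(values, index=matrix.index), "higher")


def score_vrs(matrix, variant: str = "vrs", seed: int = 0) -> ScoreTable:
    """VRS / wVRS / mVRS per gene; lower = cleaner two-way split."""
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    if x.shape[1] < 4:
        raise ValueError("variance reduction scores need at least 4 samples")
    if variant in ("vrs", "wvrs"):
        vrs, wvrs = split_scores(x)
        values = vrs if variant == "vrs" else wvrs
    elif variant == "mvrs":
        values = mvrs_scores(x, seed=seed)
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    return ScoreTable(variant, pd.Series(values, index=matrix.index), "lower")


def bimodality_coefficient(values) -> float:
    """BC = (skew^2 + 1) / (kurt + 3(n-1)^2 / ((n-2)(n-3))).

    Bias-corrected sample skewness and excess kurtosis; in (0, 1] for large
    samples, ~5/9 at the uniform, -> 1 for a balanced two-point mass.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("bimodality coefficient needs at least 4 values")
    if np.ptp(x) == 0:
        return float("nan")
    g = stats.skew(x, bias=False)
    k = stats.kurtosis(x, fisher=True, bias=False)
    return float((g**2 + 1.0) / (k + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def score_bimodality_coefficient(matrix) -> ScoreTable:
    matrix = pd.DataFrame(matrix)
    x = _as_array(matrix)
    G, n = x.shape
    if n < 4:
        raise ValueError("bimodality coefficient needs at least 4 samples")
    values = np.full(G, np.nan)
    ok = np.ptp(x, axis=1) > 0
    if ok.any():
        g = stats.skew(x[ok], axis=1, bias=False)
        k = stats.kurtosis(x[ok], axis=1, fisher=True, bias=False)
        values[ok] = (g**2 + 1.0) / (k + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return ScoreTable("bc", pd.Series(values, index=matrix.index), "higher")


# method name -> scoring callable taking (matrix, seed)
METHODS: dict[str, object] = {
    "m": lambda mat, seed=0: score_location(mat, "mean"),
    "q3": lambda mat, seed=0: score_location(mat, "q3"),
    "sd": lambda mat, seed=0: score_spread(mat, "sd"),
    "iqr": lambda mat, seed=0: score_spread(mat, "iqr"),
    "ent": lambda mat, seed=0: score_entropy(mat),
    "coex1": lambda mat, seed=0: score_coexpression(mat, "coex1"),
    "coex2": lambda mat, seed=0: score_coexpression(mat, "coex2"),
    "dip": lambda mat, seed=0: score_dip(mat),
    "bi": lambda mat, seed=0: score_bimodality_index(mat),
    # single EM start from a 2-means split: the cheap BI used in the
    # subsampling designs, where the 10-start grid is too slow
    "bi_kmeans": lambda mat, seed=0: score_bimodality_index(
        mat, starts="kmeans_single"
    ),
    "vrs": lambda mat, seed=0: score_vrs(mat, "vrs"),
    "wvrs": lambda mat, seed=0: score_vrs(mat, "wvrs"),
    "mvrs": lambda mat, seed=0: score_vrs(mat, "mvrs", seed=seed),
    "bc": lambda mat, seed=0: score_bimodality_coefficient(mat),
}


def score_matrix(matrix, method: str, seed: int = 0) -> ScoreTable:
    """Score every gene of a matrix with one of the 13 unsupervised methods."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        ) from None
    return fn(matrix, seed=seed)
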