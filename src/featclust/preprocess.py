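"""Count preprocessing: low-expression filter, size factors, VST.

The pipeline for raw RNA-seq counts is filter -> median-of-ratios size
factors -> normalization -> variance stabilizing transform (VST).  The VST
assumes the negative-binomial mean-variance relation h(mu) = mu + alpha*mu^2
with a single common dispersion alpha and applies

    y(x) = integral_0^x h(u)^(-1/2) du = (2/sqrt(alpha)) * asinh(sqrt(alpha*x)),

which is monotone, equals 2*sqrt(x) in the Poisson limit alpha -> 0, and
makes the per-gene SD approximately independent of the mean on NB data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SizeFactors",
    "VSTParams",
    "filter_low_expressed",
    "size_factors_median_of_ratios",
    "normalize",
    "vst",
    "log2_transform",
    "estimate_common_dispersion",
    "DISPERSION_FLOOR",
]

DISPERSION_FLOOR = 1e-8

# Per-sample positive scaling constants, indexed by sample id.
SizeFactors = pd.Series


@dataclass(frozen=True)
class VSTParams:
    """Common NB dispersion used in the mean-variance relation."""

    dispersion_common: float

    def __post_init__(self) -> None:
        if not self.dispersion_common > 0:
            raise ValueError("dispersion_common must be > 0")


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")


def filter_low_expressed(
    counts: pd.DataFrame,
    sample_quantile: float = 0.25,
    drop_fraction: float = 0.25,
) -> pd.DataFrame:
    """Remove genes that sit below the per-sample expression quantile often.

    Each gene is scored by the number of samples in which its value falls
    strictly below that sample's ``sample_quantile`` percentile of gene
    values (linear-interpolation quantile).  The ``drop_fraction`` of genes
    with the highest score is removed; survivors keep their input order.
    Boundary ties are resolved by dropping genes with lower total count
    first, then by later input position, so the output is deterministic.
    """
    _check_counts(counts)
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in [0, 1)")
    if not 0.0 <= sample_quantile <= 1.0:
        raise ValueError("sample_quantile must lie in [0, 1]")
    if drop_fraction == 0.0:
        return counts.copy()

    values = counts.to_numpy(dtype=float)
    g = values.shape[0]
    thresholds = np.quantile(values, sample_quantile, axis=0)  # per sample
    score = (values < thresholds[None, :]).sum(axis=1)

    n_drop = int(np.floor(drop_fraction * g))
    if n_drop == 0:
        return counts.copy()
    total = values.sum(axis=1)
    # Drop the n_drop worst: highest score, then lowest total count, then
    # earliest input position.
    order = np.lexsort((np.arange(g), total, -score))
    drop = np.zeros(g, dtype=bool)
    drop[order[:n_drop]] = True
    return counts.loc[~drop]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> SizeFactors:
    """Median-of-ratios size factors with a geometric-mean reference.

    K_iR is the geometric mean of gene i across samples; s_j is the median
    over genes with K_iR != 0 of K_ij / K_iR.
    """
    _check_counts(counts)
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene with all-positive counts: geometric-mean reference "
            "is zero for every gene"
        )
    ref = np.exp(np.log(values[positive]).mean(axis=1))  # K_iR
    ratios = values[positive] / ref[:, None]
    s = np.median(ratios, axis=0)
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("degenerate size factors (zero median ratio)")
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, s: SizeFactors) -> pd.DataFrame:
    """Divide each sample's column by its size factor."""
    if len(s) != counts.shape[1]:
        raise ValueError("size factors and samples do not match")
    sv = np.asarray(s, dtype=float)
    if np.any(sv <= 0) or not np.all(np.isfinite(sv)):
        raise ValueError("size factors must be positive and finite")
    return counts / sv


def vst(
    counts: pd.DataFrame,
    params: VSTParams,
    s: SizeFactors | None = None,
) -> pd.DataFrame:
    """Variance stabilizing transform of (normalized) counts.

    Applies y(x) = (2/sqrt(alpha)) * asinh(sqrt(alpha*x)) to the normalized
    counts (``counts / s``; pass ``s=None`` for already-normalized input).
    """
    a = params.dispersion_common
    x = counts if s is None else normalize(counts, s)
    xv = x.to_numpy(dtype=float)
    if (xv < 0).any():
        raise ValueError("vst input must be nonnegative")
    y = (2.0 / np.sqrt(a)) * np.arcsinh(np.sqrt(a * xv))
    return pd.DataFrame(y, index=x.index, columns=x.columns)


def log2_transform(
    counts: pd.DataFrame,
    s: SizeFactors | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(x + pseudocount) of normalized counts (comparison transform)."""
    x = counts if s is None else normalize(counts, s)
    return np.log2(x + pseudocount)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    s: SizeFactors | None = None,
    floor: float = DISPERSION_FLOOR,
) -> VSTParams:
    """Method-of-moments common NB dispersion.

    Per gene, alpha_i = max(0, (var_i - mean_i) / mean_i^2) on normalized
    counts (NB: var = mu + alpha*mu^2); the common alpha is the median over
    genes with positive mean, floored at a small positive constant.
    """
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    x = (counts if s is None else normalize(counts, s)).to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    ok = mean > 0
    if not ok.any():
        return VSTParams(floor)
    alpha = np.maximum(0.0, (var[ok] - mean[ok]) / mean[ok] ** 2)
    return VSTParams(max(float(np.median(alpha)), floor))
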