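"""Synthetic datasets with the statistical structure the benchmark assumes.

Two generators are provided:

* a Gaussian two-group design in which a small block of informative features
  is mean-shifted in one group while everything else is pure N(0, sd) noise —
  the classic "needle in a haystack" setting for feature selection before
  clustering;
* a negative-binomial count matrix with two subtypes, per-sample library-size
  factors and a configurable fraction of differentially expressed genes,
  mirroring the NB GLM used by the supervised control, so size-factor
  estimation, the variance stabilizing transform and the supervised test can
  all be exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GaussianSimConfig",
    "NBSimConfig",
    "LabeledDataset",
    "simulate_gaussian_two_group",
    "simulate_nb_counts",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_labels_tsv",
    "read_labels_tsv",
]


@dataclass(frozen=True)
class GaussianSimConfig:
    """Two-group Gaussian design.

    Defaults are the benchmark's study conditions: 100 samples (50 per
    group), 10,000 features of which the first 100 are informative, a one
    noise-SD mean shift on informative features in group B, and 40
    replicates.
    """

    n_per_group: int = 50
    n_features: int = 10_000
    n_informative: int = 100
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_replicates: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative must lie in [0, n_features]; got "
                f"{self.n_informative} with n_features={self.n_features}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


@dataclass(frozen=True)
class NBSimConfig:
    """Two-subtype negative-binomial count design.

    Counts follow K_ij ~ NB(mean = s_j * q_ij, dispersion = alpha_i) with
    var = mu + alpha * mu^2.  Per-gene base means are log-normal
    (``base_mean_log_mean``/``base_mean_log_sd`` on the natural-log scale),
    a ``frac_de`` fraction of genes has its group-B mean scaled by
    2**log2_fc, and size factors are drawn log-uniformly on
    ``size_factor_range``.
    """

    n_samples_a: int = 50
    n_samples_b: int = 50
    n_genes: int = 5_000
    frac_de: float = 0.1
    log2_fc: float = 1.0
    base_mean_log_mean: float = 5.0
    base_mean_log_sd: float = 1.5
    dispersion: float | Sequence[float] = 0.15
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_a < 1 or self.n_samples_b < 1:
            raise ValueError("group sizes must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if np.any(disp <= 0) or not np.all(np.isfinite(disp)):
            raise ValueError("dispersion must be positive and finite")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must satisfy 0 < lo <= hi")


@dataclass
class LabeledDataset:
    """A gene x sample matrix with per-sample labels and known truth.

    ``matrix`` is the working expression matrix (genes as rows).  For count
    designs ``counts`` holds the raw integers and ``size_factors`` the true
    per-sample depth factors; ``informative_genes`` lists the genes that
    genuinely carry the group signal.
    """

    matrix: pd.DataFrame
    labels: pd.Series
    informative_genes: pd.Index
    counts: pd.DataFrame | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("labels length must equal the number of samples")
        if not pd.Index(self.informative_genes).isin(self.matrix.index).all():
            raise ValueError("informative_genes must be a subset of the genes")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"g{i + 1:0{width}d}" for i in range(n)], name="gene_id")


def _sample_ids(labels: Sequence[str]) -> pd.Index:
    counts: dict[str, int] = {}
    out = []
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
        out.append(f"{lab}{counts[lab]:03d}")
    return pd.Index(out, name="sample_id")


def simulate_gaussian_two_group(config: GaussianSimConfig) -> LabeledDataset:
    """Draw one replicate of the Gaussian two-group design.

    Returns a ``n_features x 2*n_per_group`` real-valued matrix.  Informative
    features (the first ``n_informative`` rows, identifiers returned
    explicitly) have population mean ``effect_size`` in group B and 0
    elsewhere; every cell has SD ``noise_sd``.
    """
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_group
    values = rng.normal(0.0, config.noise_sd, size=(config.n_features, n))
    labels = ["A"] * config.n_per_group + ["B"] * config.n_per_group
    values[: config.n_informative, config.n_per_group:] += config.effect_size

    genes = _gene_ids(config.n_features)
    samples = _sample_ids(labels)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    lab = pd.Series(labels, index=samples, name="label")
    return LabeledDataset(matrix, lab, genes[: config.n_informative])


def simulate_nb_counts(config: NBSimConfig) -> LabeledDataset:
    """Draw a two-subtype NB count matrix with library-size variation.

    The expected count of gene i in sample j is ``s_j * q_ij`` where q_ij is
    the gene's subtype mean; DE genes (the first ``frac_de * n_genes`` rows)
    have the group-B mean scaled by ``2**log2_fc`` before size-factor
    scaling.  Counts are NB with var = mu + alpha_i * mu^2.
    """
    rng = np.random.default_rng(config.seed)
    n_a, n_b, g = config.n_samples_a, config.n_samples_b, config.n_genes
    n = n_a + n_b

    base = rng.lognormal(config.base_mean_log_mean, config.base_mean_log_sd, g)
    n_de = int(round(config.frac_de * g))
    fc = np.ones(g)
    fc[:n_de] = 2.0 ** config.log2_fc

    lo, hi = config.size_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    alpha = np.broadcast_to(
        np.atleast_1d(np.asarray(config.dispersion, dtype=float)), (g,)
    ).copy()

    q = np.empty((g, n))
    q[:, :n_a] = base[:, None]
    q[:, n_a:] = (base * fc)[:, None]
    mu = q * s[None, :]

    # NB via gamma-Poisson: shape 1/alpha, scale alpha*mu.
    lam = rng.gamma(shape=1.0 / alpha[:, None], scale=alpha[:, None] * mu)
    counts = rng.poisson(lam).astype(np.int64)

    genes = _gene_ids(g)
    labels = ["A"] * n_a + ["B"] * n_b
    samples = _sample_ids(labels)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    lab = pd.Series(labels, index=samples, name="label")
    sf = pd.Series(s, index=samples, name="size_factor")
    return LabeledDataset(
        matrix=counts_df,
        labels=lab,
        informative_genes=genes[:n_de],
        counts=counts_df,
        size_factors=sf,
    )


# --- TSV dialect: genes x samples, header row of sample IDs, first column
# gene IDs; labels as two-column (sample_id, label). ---

def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample_id")


def read_labels_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("label")
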