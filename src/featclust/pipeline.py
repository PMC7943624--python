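"""End-to-end runs from a config: filter -> normalize -> VST -> score ->
select -> cluster -> evaluate.

The supervised control consumes filtered raw counts with size-factor
offsets, while all unsupervised methods consume the variance-stabilized
matrix.  For real-valued (non-count) input the preprocessing stage is
bypassed and the supervised control falls back to a Welch t-test, which is
logged prominently.  A run is fully determined by its config and master
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import adjusted_rand_index, nssg
from .cluster import hierarchical_partition, kmeans_partition
from .nbglm import supervised_pvalues, welch_pvalues
from .preprocess import (
    estimate_common_dispersion,
    filter_low_expressed,
    log2_transform,
    normalize,
    size_factors_median_of_ratios,
    vst,
)
from .scores import ScoreTable, random_selection, score_matrix, select_top
from .simulate import read_labels_tsv, read_matrix_tsv

logger = logging.getLogger("featclust")

__all__ = ["RunConfig", "run_pipeline"]

_UNSUPERVISED = (
    "m", "q3", "sd", "iqr", "ent", "coex1", "coex2",
    "dip", "bi", "vrs", "wvrs", "mvrs", "bc",
)


@dataclass
class RunConfig:
    """Configuration of one benchmark run (YAML-serializable)."""

    counts_path: str
    labels_path: str | None = None
    driver_genes_path: str | None = None
    matrix_is_counts: bool = True
    filter_quantile: float = 0.25
    drop_fraction: float = 0.25
    transform: str = "vst"  # vst | log2 | none
    methods: tuple[str, ...] = _UNSUPERVISED
    include_supervised: bool = True
    include_random: bool = True
    k_genes: tuple[int, ...] = (100, 1000, 3000)
    cluster_method: str = "ward"  # ward | kmeans
    distance: str = "euclidean"
    n_random_repeats: int = 1000
    master_seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("methods", "k_genes"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate(self, n_genes: int) -> None:
        for m in self.methods:
            if m not in _UNSUPERVISED:
                raise ValueError(f"unknown method in config: {m!r}")
        if self.transform not in ("vst", "log2", "none"):
            raise ValueError(f"unknown transform: {self.transform!r}")
        keep = (
            n_genes - int(np.floor(self.drop_fraction * n_genes))
            if self.matrix_is_counts
            else n_genes
        )
        for k in self.k_genes:
            if k > keep:
                raise ValueError(
                    f"k_genes={k} exceeds the {keep} genes that survive "
                    "filtering"
                )


def _cluster(matrix, cfg: RunConfig) -> pd.Series:
    if cfg.cluster_method == "ward":
        return hierarchical_partition(matrix, distance=cfg.distance, k=2)
    if cfg.cluster_method == "kmeans":
        return kmeans_partition(matrix, k=2, seed=cfg.master_seed)
    raise ValueError(f"unknown cluster_method: {cfg.cluster_method!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full benchmark for one dataset; returns the report dict.

    The report maps (method, k) to ARI (when labels are available) and
    NSSG, carries the random-selection reference percentiles, and is
    written as JSON plus per-method selection TSVs when ``cfg.outdir`` is
    set.
    """
    counts = read_matrix_tsv(cfg.counts_path)
    labels = read_labels_tsv(cfg.labels_path) if cfg.labels_path else None
    if labels is not None:
        labels = labels.loc[counts.columns]
    cfg.validate(counts.shape[0])

    if cfg.matrix_is_counts:
        logger.info(
            "filtering %d genes (quantile=%.2f, drop=%.2f)",
            counts.shape[0], cfg.filter_quantile, cfg.drop_fraction,
        )
        filtered = filter_low_expressed(
            counts, cfg.filter_quantile, cfg.drop_fraction
        )
        s = size_factors_median_of_ratios(filtered)
        if cfg.transform == "vst":
            params = estimate_common_dispersion(filtered, s)
            logger.info("VST with common dispersion %.4g", params.dispersion_common)
            expr = vst(filtered, params, s)
        elif cfg.transform == "log2":
            expr = log2_transform(filtered, s)
        else:
            expr = normalize(filtered, s)
    else:
        logger.warning(
            "input is a real-valued matrix: preprocessing bypassed and the "
            "supervised control uses a Welch t-test instead of the NB GLM"
        )
        filtered, s, expr = None, None, counts

    tables: dict[str, ScoreTable] = {}
    for method in cfg.methods:
        logger.info("scoring with %s", method)
        tables[method] = score_matrix(expr, method, seed=cfg.master_seed)
    if cfg.include_supervised and labels is not None:
        if cfg.matrix_is_counts:
            pvals = supervised_pvalues(filtered, labels, s)
            tables["pval"] = ScoreTable("pval", pvals, "lower")
        else:
            tables["pval"] = ScoreTable(
                "pval", welch_pvalues(expr, labels), "lower"
            )

    report: dict = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "n_genes_scored": int(expr.shape[0]),
        "n_samples": int(expr.shape[1]),
        "results": [],
        "selections": {},
    }
    rng_rand = np.random.default_rng(cfg.master_seed)

    for k in cfg.k_genes:
        for method, table in tables.items():
            sel = select_top(table, k)
            part = _cluster(expr.loc[sel], cfg)
            entry = {
                "method": method,
                "k": int(k),
                "nssg": nssg(part),
            }
            if labels is not None:
                entry["ari"] = adjusted_rand_index(part, labels)
            report["results"].append(entry)
            report["selections"][f"{method}_{k}"] = list(map(str, sel))
        if cfg.include_random and labels is not None:
            aris = []
            for _ in range(cfg.n_random_repeats):
                sel = random_selection(
                    expr.index, k, int(rng_rand.integers(2**31))
                )
                part = _cluster(expr.loc[sel], cfg)
                aris.append(adjusted_rand_index(part, labels))
            aris = np.asarray(aris)
            report["results"].append(
                {
                    "method": "rand",
                    "k": int(k),
                    "ari": float(aris.mean()),
                    "ari_q25": float(np.quantile(aris, 0.25)),
                    "ari_q50": float(np.quantile(aris, 0.50)),
                    "ari_q75": float(np.quantile(aris, 0.75)),
                    "n_repeats": int(cfg.n_random_repeats),
                }
            )

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        rows = [r for r in report["results"]]
        pd.DataFrame(rows).to_csv(out / "results.tsv", sep="\t", index=False)
        logger.info("report written to %s", out)
    return report
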