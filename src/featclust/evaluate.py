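"""Evaluation harness: ARI, NSSG, overlap, ranks, and the study designs.

Clustering performance is measured with the adjusted Rand index (ARI)
against a gold-standard partition; the number of samples in the smallest
group (NSSG) diagnoses outlier-driven splits.  Method similarity is the
percentage overlap of equal-size selections.  The experimental designs are
(a) the Gaussian simulation study — clustering on all features, informative
features only, and SD-selected top-k sweeps — and (b) stratified bootstrap
subsampling (balanced 50/50 or skewed 25/75) with per-replicate scoring,
selection, clustering, and paired t-tests between methods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .cluster import hierarchical_partition, ward_cut_from_condensed
from .scores import ScoreTable, score_matrix, select_top
from .simulate import GaussianSimConfig, LabeledDataset, simulate_gaussian_two_group

__all__ = [
    "adjusted_rand_index",
    "nssg",
    "overlap_percentage",
    "characterize_selection",
    "rank_methods",
    "SubsampleDesign",
    "subsample_experiment",
    "paired_method_tests",
    "pairwise_method_tests",
    "running_mean",
    "ari_vs_ngenes_curve",
    "enrichment_test",
    "SimulationStudyResult",
    "run_simulation_study",
]


def adjusted_rand_index(p1, p2) -> float:
    """Permutation-model ARI between two partitions of the same samples.

    1 for identical partitions (up to label names), ~0 for independent
    ones.  Accepts label arrays or Series; Series are aligned on their
    sample index and must cover the same samples.
    """
    a, b = pd.Series(p1), pd.Series(p2)
    if isinstance(p1, pd.Series) and isinstance(p2, pd.Series):
        if set(a.index) != set(b.index):
            raise ValueError("partitions cover different sample sets")
        b = b.loc[a.index]
    elif len(a) != len(b):
        raise ValueError("partitions have different lengths")
    return float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))


def nssg(p) -> int:
    """Number of samples in the smallest of the two groups of a partition."""
    counts = pd.Series(p).value_counts()
    if len(counts) != 2:
        raise ValueError(
            f"NSSG is defined for 2-group partitions; got {len(counts)} groups"
        )
    return int(counts.min())


def overlap_percentage(sel1, sel2) -> float:
    """Percentage of genes selected by both methods (equal-size selections)."""
    s1, s2 = pd.Index(sel1), pd.Index(sel2)
    if len(s1) != len(s2):
        raise ValueError("overlap is defined for equal-size selections")
    if len(s1) == 0:
        raise ValueError("empty selections")
    return 100.0 * len(s1.intersection(s2)) / len(s1)


def characterize_selection(matrix, sel) -> pd.DataFrame:
    """Quartiles of per-gene mean and SD for a selection vs the ALL baseline.

    Returns a DataFrame indexed by q25/q50/q75 with a (group, statistic)
    column MultiIndex, group in {selection, all}.
    """
    matrix = pd.DataFrame(matrix)
    sel = pd.Index(sel)
    unknown = sel.difference(matrix.index)
    if len(unknown) > 0:
        raise ValueError(f"unknown gene ids in selection: {list(unknown[:5])}")
    per_gene = pd.DataFrame(
        {
            "mean": matrix.mean(axis=1),
            "sd": matrix.std(axis=1, ddof=1),
        }
    )
    qs = [0.25, 0.5, 0.75]
    out = {}
    for group, genes in (("selection", sel), ("all", matrix.index)):
        sub = per_gene.loc[genes]
        for col in ("mean", "sd"):
            out[(group, col)] = sub[col].quantile(qs).to_numpy()
    return pd.DataFrame(out, index=pd.Index(["q25", "q50", "q75"]))


def rank_methods(ari_table: pd.DataFrame):
    """Within-row ranks (descending ARI, average ties) and per-method means.

    Rows are dataset x gene-count settings, columns are methods.  Returns
    (rank table, mean ranks); mean ranks over m methods average to (m+1)/2.
    """
    if ari_table.isna().any().any():
        raise ValueError("ARI table has missing cells")
    ranks = ari_table.apply(
        lambda row: pd.Series(
            stats.rankdata(-row.to_numpy(), method="average"), index=row.index
        ),
        axis=1,
    )
    return ranks, ranks.mean(axis=0).rename("mean_rank")


@dataclass(frozen=True)
class SubsampleDesign:
    """Stratified bootstrap design: fixed per-subtype draws with replacement.

    ``size_a``/``size_b`` are the number of samples drawn from the first
    and second label level (levels sorted).  The balanced design draws
    50/50, the skewed design 25 from one subtype and 75 from the other.
    """

    mode: str
    size_a: int
    size_b: int
    n_datasets: int = 100
    with_replacement: bool = True
    seed: int = 0

    @classmethod
    def balanced(cls, n_per_group: int = 50, n_datasets: int = 100, seed: int = 0):
        return cls("balanced", n_per_group, n_per_group, n_datasets, True, seed)

    @classmethod
    def skewed(
        cls, n_small: int = 25, n_large: int = 75, n_datasets: int = 100,
        seed: int = 0,
    ):
        return cls("skewed", n_small, n_large, n_datasets, True, seed)


def _stratified_bootstrap(
    matrix: pd.DataFrame, labels: pd.Series, design: SubsampleDesign, rng
):
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("subsampling needs exactly two subtypes")
    cols, labs = [], []
    for level, size in zip(levels, (design.size_a, design.size_b)):
        pool = np.flatnonzero((labels == level).to_numpy())
        if pool.size == 0:
            raise ValueError(f"subtype {level!r} has no samples")
        take = rng.choice(pool, size=size, replace=design.with_replacement)
        cols.extend(take)
        labs.extend([level] * size)
    sub = matrix.iloc[:, cols].copy()
    # bootstrap may duplicate samples; suffixed ids keep columns distinct
    sub.columns = [f"{c}.r{i}" for i, c in enumerate(sub.columns)]
    return sub, pd.Series(labs, index=sub.columns, name="label")


def subsample_experiment(
    dataset: LabeledDataset,
    design: SubsampleDesign,
    methods,
    k_genes: int = 1000,
    distance: str = "euclidean",
) -> pd.DataFrame:
    """Per-replicate ARI and NSSG for each method under a bootstrap design.

    For each replicate: draw the stratified bootstrap, re-score genes with
    each method, select the top ``k_genes``, cluster (Ward/Euclidean,
    k = 2), and record ARI against the subtype labels and NSSG.  Returns a
    DataFrame with a (method, metric) column MultiIndex.
    """
    out: dict[tuple[str, str], list[float]] = {
        (m, metric): [] for m in methods for metric in ("ari", "nssg")
    }
    for rep in range(design.n_datasets):
        rng = np.random.default_rng(design.seed + rep)
        sub, labs = _stratified_bootstrap(dataset.matrix, dataset.labels, design, rng)
        for method in methods:
            table = score_matrix(sub, method, seed=design.seed + rep)
            sel = select_top(table, k_genes)
            part = hierarchical_partition(sub.loc[sel], distance=distance, k=2)
            out[(method, "ari")].append(adjusted_rand_index(part, labs))
            out[(method, "nssg")].append(nssg(part))
    df = pd.DataFrame(out)
    df.index.name = "replicate"
    return df


def paired_method_tests(x, y):
    """One-sample t-test on paired per-replicate differences.

    Returns (mean difference, two-sided p).  Degenerate zero-variance
    differences give p = 1 when the mean difference is 0 and p = 0
    otherwise.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 paired observations")
    d = a - b
    mean = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        return mean, (1.0 if np.isclose(mean, 0.0) else 0.0)
    res = stats.ttest_1samp(d, popmean=0.0)
    return mean, float(res.pvalue)


def pairwise_method_tests(results: pd.DataFrame, metric: str = "ari"):
    """Mean paired differences (row - column) and p-values for all pairs."""
    methods = sorted({m for m, _ in results.columns})
    diff = pd.DataFrame(np.nan, index=methods, columns=methods)
    pval = pd.DataFrame(np.nan, index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for mj in methods[i + 1 :]:
            d, p = paired_method_tests(
                results[(mi, metric)], results[(mj, metric)]
            )
            diff.loc[mi, mj] = d
            diff.loc[mj, mi] = -d
            pval.loc[mi, mj] = pval.loc[mj, mi] = p
    return diff, pval


def running_mean(values, window: int) -> np.ndarray:
    """Centered running mean, truncated at the edges; window = 1 is identity."""
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > v.size:
        raise ValueError("running-mean window exceeds the curve length")
    half = (window - 1) // 2
    out = np.empty_like(v)
    for i in range(v.size):
        lo = max(0, i - half)
        hi = min(v.size, i + (window - half))
        out[i] = v[lo:hi].mean()
    return out


def _cumulative_euclidean_ari(
    x_ordered: np.ndarray, grid: np.ndarray, labels: np.ndarray, k: int = 2
) -> np.ndarray:
    """ARI of Ward/Euclidean clustering on growing top-k gene sets.

    ``x_ordered`` is genes x samples with rows already in rank order; the
    squared sample-sample distances are accumulated blockwise over the
    grid so each clustering reuses all previous gene contributions.
    """
    n = x_ordered.shape[1]
    iu = np.triu_indices(n, k=1)
    gram = np.zeros((n, n))
    sq = np.zeros(n)
    aris = np.empty(grid.size)
    prev = 0
    for gi, g in enumerate(grid):
        block = x_ordered[prev:g]
        if block.shape[0] > 0:
            gram += block.T @ block
            sq += (block**2).sum(axis=0)
        prev = g
        d2 = sq[:, None] + sq[None, :] - 2.0 * gram
        dvec = np.sqrt(np.maximum(d2[iu], 0.0))
        part = ward_cut_from_condensed(dvec, k)
        aris[gi] = adjusted_rand_score(part, labels)
    return aris


def ari_vs_ngenes_curve(
    matrix,
    scores: ScoreTable,
    labels,
    n_points: int = 1000,
    running_mean_window: int = 100,
    k: int = 2,
):
    """ARI as the selection grows from 2 genes to the full ranking.

    Scoring is done once; the selection is re-cut from the full ranking at
    ``n_points`` evenly spaced gene counts (deduplicated), each clustered
    with Ward/Euclidean and compared to ``labels``; a centered running mean
    smooths the raw curve.  Returns a DataFrame (n_genes, ari, smoothed).
    """
    matrix = pd.DataFrame(matrix)
    ranking = scores.ranking()
    total = len(ranking)
    if total < 2:
        raise ValueError("need at least 2 scorable genes")
    grid = np.unique(np.linspace(2, total, min(n_points, total - 1)).astype(int))
    labels = pd.Series(labels).loc[matrix.columns].to_numpy()
    x_ordered = matrix.loc[ranking].to_numpy(dtype=float)
    aris = _cumulative_euclidean_ari(x_ordered, grid, labels, k=k)
    smooth = running_mean(aris, running_mean_window)
    return pd.DataFrame({"n_genes": grid, "ari": aris, "smoothed": smooth})


def enrichment_test(sel, special_genes, universe):
    """One-sided Fisher enrichment of a gene set within a selection.

    Returns (proportion of the selection that is special, one-sided
    'greater' p) from the 2x2 selected/not x special/not table.
    """
    uni = pd.Index(universe)
    if len(uni) == 0:
        raise ValueError("empty universe")
    sel = pd.Index(sel)
    spec = pd.Index(special_genes)
    if len(sel.difference(uni)) or len(spec.difference(uni)):
        raise ValueError("selection and special genes must lie in the universe")
    a = len(sel.intersection(spec))
    b = len(sel) - a
    c = len(spec) - a
    d = len(uni) - len(sel) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return a / len(sel), float(p)


@dataclass
class SimulationStudyResult:
    """Per-replicate ARIs for the Gaussian simulation study conditions."""

    ari_informative: np.ndarray
    ari_all: np.ndarray
    sd_sweep: pd.DataFrame | None  # replicates x k grid

    @property
    def mean_ari_informative(self) -> float:
        return float(self.ari_informative.mean())

    @property
    def mean_ari_all(self) -> float:
        return float(self.ari_all.mean())

    def mean_sweep(self) -> pd.Series:
        if self.sd_sweep is None:
            raise ValueError("study was run without the SD sweep")
        return self.sd_sweep.mean(axis=0).rename("mean_ari")


def run_simulation_study(
    cfg: GaussianSimConfig,
    sd_grid=None,
    include_sd_sweep: bool = True,
) -> SimulationStudyResult:
    """The Gaussian simulation study over ``cfg.n_replicates`` replicates.

    Each replicate is clustered (Ward/Euclidean, cut to 2) on (a) the
    informative features only, (b) all features, and (c) the k features
    with the highest SD for every k in ``sd_grid`` (default 100, 200, ...,
    n_features).  Replicate r uses seed ``cfg.seed + r``.
    """
    if include_sd_sweep:
        if sd_grid is None:
            sd_grid = np.arange(100, cfg.n_features + 1, 100)
        sd_grid = np.asarray(sd_grid, dtype=int)
        if sd_grid.size and (sd_grid.min() < 1 or sd_grid.max() > cfg.n_features):
            raise ValueError("sd_grid must lie within [1, n_features]")

    ari_inf = np.empty(cfg.n_replicates)
    ari_all = np.empty(cfg.n_replicates)
    sweep_rows = []
    for r in range(cfg.n_replicates):
        ds = simulate_gaussian_two_group(replace(cfg, seed=cfg.seed + r))
        x = ds.matrix.to_numpy()
        truth = ds.labels.to_numpy()

        if cfg.n_informative >= 2:
            part = hierarchical_partition(
                ds.matrix.loc[ds.informative_genes], k=2
            )
            ari_inf[r] = adjusted_rand_index(part, ds.labels)
        else:
            ari_inf[r] = np.nan

        part_all = hierarchical_partition(ds.matrix, k=2)
        ari_all[r] = adjusted_rand_index(part_all, ds.labels)

        if include_sd_sweep and sd_grid.size:
            order = np.argsort(-x.std(axis=1, ddof=1), kind="stable")
            aris = _cumulative_euclidean_ari(x[order], sd_grid, truth)
            sweep_rows.append(aris)

    sweep = (
        pd.DataFrame(sweep_rows, columns=pd.Index(sd_grid, name="k"))
        if sweep_rows
        else None
    )
    return SimulationStudyResult(ari_inf, ari_all, sweep)
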