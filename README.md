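# featclust

Unsupervised gene selection for clustering-based subtype discovery in
RNA-seq expression data — the methods, the controls, and the evaluation
harness to compare them.

## The problem

Clustering tumor samples on genome-wide expression can reveal disease
subtypes, but only a small fraction of genes carries subtype information;
the rest dilute the signal. Because the subtype labels are unknown at
selection time, genes must be ranked by *unsupervised* scores. This package
implements thirteen such per-gene scores, organized by the idea behind
them:

| idea | methods |
|---|---|
| high expression | mean (M), third quartile (Q3) |
| high variability | SD, IQR, quadratic Rényi entropy (ENT) |
| co-expression | median \|Spearman\| (CoEx1), cubed-similarity sum (CoEx2) |
| multi/bimodality | dip test (DIP), bimodality index (BI), bimodality coefficient (BC), variance reduction scores (VRS, wVRS, mVRS) |

plus a supervised positive control (per-gene negative-binomial GLM Wald
test, PVAL) and negative controls (random selection RAND, no selection
ALL). Samples are clustered on the top-k ranked genes (Ward/Euclidean by
default; Ward on 1−|Spearman ρ| and k-means are available) and the
partition is scored against known labels with the adjusted Rand index
(ARI):

```
ARI = (Σ_ij C(n_ij,2) − E) / (max − E),   E = Σ_i C(a_i,2) Σ_j C(b_j,2) / C(n,2)
```

Representative score definitions, for a gene with values x₁…xₙ:

- dip: `D = min over unimodal CDFs G of sup_x |F_n(x) − G(x)|`, with
  Monte-Carlo p-values against the uniform null;
- bimodality index: fit `f(x) = p·N(μ_A,σ) + (1−p)·N(μ_B,σ)` by EM, then
  `BI = p(1−p)·|μ_A−μ_B|/σ`;
- entropy: `ENT = −log( 2/(n(n−1)h) Σ_{i<j} K((x_i−x_j)/h) )` with the
  rectangular kernel and Silverman bandwidth `h = 1.06·σ̂·n^(−1/5)`;
- variance reduction: `VRS = WSS/TSS` under the optimal two-means split.

Count preprocessing follows standard RNA-seq practice: a low-expression
filter (genes often below the per-sample 25th percentile are dropped),
median-of-ratios size factors `s_j = median_i K_ij/K_iR` with geometric-mean
reference `K_iR`, and the NB variance-stabilizing transform
`y(x) = (2/√α)·asinh(√(αx))`.

## Worked example

```python
import featclust as fc

# two-subtype NB count cohort with 2% DE genes and library-size variation
ds = fc.simulate_nb_counts(fc.NBSimConfig(
    n_genes=6000, frac_de=0.02, log2_fc=0.8, dispersion=0.2, seed=7))

counts = fc.filter_low_expressed(ds.counts)          # 6000 -> 4500 genes
s = fc.size_factors_median_of_ratios(counts)
expr = fc.vst(counts, fc.estimate_common_dispersion(counts, s), s)

for method in ("sd", "dip", "mvrs"):
    sel = fc.select_top(fc.score_matrix(expr, method), 1000)
    part = fc.hierarchical_partition(expr.loc[sel])   # Ward/Euclidean, k=2
    print(method, round(fc.adjusted_rand_index(part, ds.labels), 3))
```

prints

```
sd 0.921
dip 0.186
mvrs 0.354
```

i.e. on this cohort the 1000 highest-SD genes recover the two subtypes
almost perfectly (ARI 0.92) while the dip-based selection, which needs
clearly bimodal genes, does not — the per-gene group shift here (log2 FC
0.8) is too small to create visible bimodality.

The full study lives in `analysis/`:

- `01_simulation_study.py` — the Gaussian needle-in-a-haystack simulation:
  clustering on the 100 truly informative of 10,000 features vs all
  features vs SD-selected top-k sweeps;
- `02_method_benchmark.py` — all 13 methods + controls × k ∈ {100, 1000,
  3000} on an NB cohort: ARI tables, method ranks, selection overlap,
  mean/SD characterization;
- `03_detailed_evaluation.py` — balanced (50/50) and skewed (25/75)
  stratified bootstrap designs with paired t-tests, ARI-vs-gene-count
  curves, and driver-panel enrichment.

Each writes its tables under `results/`. A CLI mirrors the stages:
`featclust simulate|preprocess|score|cluster|evaluate|benchmark`.

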