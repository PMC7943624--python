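# Methods

This note documents the models, estimators, numerical choices and
limitations behind `featclust`. Everything stated here is computed by the
test suite or the analysis scripts; nothing is quoted from elsewhere.

## Synthetic data

**Gaussian two-group design** (`simulate_gaussian_two_group`). The study
condition is 100 samples (50 per group) × 10,000 features; features are
iid N(0, σ) noise except the first `n_informative = 100`, which are
N(effect, σ) in group B with `effect = 1` and `σ = 1`; 40 replicates,
replicate r seeded with `seed + r`. Informative genes are the first rows by
convention, and their identifiers are returned explicitly so nothing
downstream depends on the ordering. No standardization is applied before
clustering the simulated values: the generator already produces
unit-variance features, and standardizing would only rescale noise.

**Negative-binomial two-subtype design** (`simulate_nb_counts`). Counts are
gamma-Poisson: K_ij ~ NB(mean = s_j·q_ij, var = μ + αμ²). Per-gene base
means are log-normal (meanlog 5, sdlog 1.5 — medians near 150 counts,
heavy right tail, as in typical bulk RNA-seq); dispersion defaults to
α = 0.15 (mid-range for bulk cohorts); size factors are drawn log-uniformly
on [0.5, 2] (about a four-fold depth range); a `frac_de` fraction of genes
has its group-B mean multiplied by 2^log2_fc. The generator returns the
true size factors and DE gene list for recovery tests.

What the generators deliberately do **not** emulate: secondary factors
(sex, age, batch) that structure real cohorts, gene–gene correlation beyond
the single group factor, and gene-length effects. Two consequences for
interpreting results: (a) passing tests show the machinery is correct, not
that any method will win on real cohorts; (b) co-expression scores look
artificially good on the NB synthetic data because the only correlation
structure present *is* the subtype signal, whereas on real data they are
known to chase other structure.

## Preprocessing

*Filter.* Each gene is scored by the number of samples in which it lies
strictly below that sample's 25th percentile of gene values
(linear-interpolation/type-7 quantiles throughout the package); the
`drop_fraction` (default 25%) of genes with the highest score is removed,
i.e. `floor(0.25·G)` genes, ties at the boundary resolved by lower total
count then earlier input position so output is deterministic. The filter
runs on raw counts, before normalization.

*Size factors.* Median-of-ratios with a geometric-mean reference: genes
with a zero anywhere drop out of the reference. No rescaling is applied
afterwards; consequently the exact equivariance property is on ratios
(multiplying one sample's counts by c multiplies its factor *relative to
any other sample's* by exactly c, while each absolute factor moves by
c^(±1/n) through the reference).

*VST.* We use y(x) = ∫₀ˣ h(μ)^(−1/2) dμ with h(μ) = μ + αμ², i.e.
`(2/√α)·asinh(√(αx))` applied to normalized counts. The square-root form is
the one that actually stabilizes a variance function h (delta method:
Var y(X) ≈ y′(μ)²·h(μ) = 1); writing the integrand as 1/h would instead
stabilize nothing of that kind, so we adopt the √ form deliberately. A
single common dispersion is used, estimated by the method of moments
(median over genes of max(0, (var−mean)/mean²) on normalized counts,
floored at 1e−8): the transform's role here is rank stabilization before
scoring, not precise per-gene inference, so a fitted mean–dispersion trend
would add machinery without changing selections.

## Scores

Directions: higher-is-better for M, Q3, SD, IQR, ENT, CoEx1/2, BI, BC (and
the dip statistic); lower-is-better for VRS, wVRS, mVRS and p-values (dip,
supervised). Degenerate genes (constant values, undefined correlations)
score NaN, are never selectable, and rank after all scorable genes.
Selection ties are broken by an optional secondary score and then input
order, making every selection deterministic.

**Dip.** The statistic is computed with the iterative greatest-convex-
minorant / least-concave-majorant algorithm on the sorted sample (O(n) per
iteration); an independent linear-programming oracle (minimize the sup-norm
band such that a convex-then-concave CDF with an atom at the mode fits
inside it, over all candidate modes) verifies it exactly on small samples
in the tests. Constant samples return the lower bound 1/(2n). P-values are
Monte-Carlo against uniform null samples of the same size: 10,000 draws by
default, generated once per sample size from a fixed internal seed and
cached. Because the null table is shared, p is a monotone step function of
the statistic; ties in p between distinct statistics are resolved by the
statistic itself (secondary sort key), so selecting by p and selecting by
the statistic give identical gene sets at fixed n.

**BI.** Equal-variance two-component Gaussian mixture by EM. Grid mode runs
10 starts with the mixing fraction at k/11, k = 1…10, each initialized by
the corresponding quantile split (component means = split means, σ = pooled
within-split SD), keeping the best log-likelihood; `kmeans_single` mode
takes one start from the exact 2-means split — this is the cheap variant
used inside the bootstrap designs. EM stops when the relative
log-likelihood change drops below 1e−8 (cap 1000 iterations); σ is floored
at 1e−6 × data SD to prevent variance collapse; p is clipped away from
{0, 1}. BI = p(1−p)·|μ_A−μ_B|/σ as such — the `sqrt_fraction` flag gives
the √(p(1−p)) variant of the original index definition.

**VRS / wVRS.** The internal 2-group split is the *global* optimum of the
one-dimensional 2-means objective, found exactly by scanning the n−1
contiguous splits of the sorted values (in 1-D the optimal clusters are
intervals). This replaces randomized k-means restarts with a deterministic
exact optimizer of the same objective; tests confirm it against exhaustive
enumeration of all bipartitions. wVRS = ½(WSS_A/n_A + WSS_B/n_B)/(TSS/n) is
used as printed and may exceed 1 for unbalanced noisy splits; no clipping.

**mVRS.** Fuzzy 2-means (fuzzifier m = 2) on the gene's values, centers
initialized from the exact 2-means split, alternating membership/center
updates until the center shift is below 1e−10 (cap 300); the score is the
fuzzy objective Σ_c Σ_i u_ic² (x_i − c_c)² over TSS. Coincident centers are
jittered once (1e−6 × SD), else NaN. The fuzzy-weighted WSS/TSS reading is
one concrete interpretation of "soft k-means variance reduction"; the flag
points are documented in the code.

**ENT.** Pairwise rectangular-kernel U-statistic with Silverman bandwidth.
If no pair falls within h the density estimate is 0 and ENT = +∞, which
simply ranks the gene at the top of the variability ordering — harmless and
extremely rare beyond tiny n. Scaling a gene by c shifts ENT by log c
(bandwidth and gaps scale together), which the tests verify.

**CoEx.** |Spearman| similarity with average ranks for ties; a constant
gene contributes 0 similarity to others and scores NaN itself. The full
G×G similarity matrix is formed, so memory is O(G²) — fine up to ~20k genes
at float64.

**BC.** Bias-corrected sample skewness and excess kurtosis; BC → 1 for a
balanced two-point mass, ≈ 1/3 at the Gaussian, ≈ 5/9 at the uniform.

**PVAL (supervised control).** Per-gene NB GLM with log link, group
indicator and log-size-factor offset; gene-wise dispersion by profile
maximum likelihood on a log grid (1e−8…50, coarse-then-fine, ~40
evaluations), group rates by Newton scoring (closed form for a two-group
design); Wald p from expected information. No empirical-Bayes shrinkage by
design — the control's job is ranking genes given labels, not stabilizing
small-cohort estimates. The implementation is fully vectorized across
genes (10,000 fits in ~10 s); statsmodels' NegativeBinomial MLE fits the
identical model per-gene and is the reference in the tests (type-I error
0.05 ± 0.02 on null NB data at 10,000 genes). For real-valued input the
pipeline substitutes a Welch t-test and logs the substitution.

## Clustering and evaluation

Ward's linkage on Euclidean sample distances is the default, cut to
exactly k = 2; Ward on the precomputed 1−|Spearman ρ| distance is accepted
on purpose despite Ward's Euclidean derivation, and k-means (best inertia
over 10 seeded restarts) is the third option. Partitions are compared only
through label-permutation-invariant quantities: ARI and NSSG (size of the
smaller group — small values flag outlier-driven splits).

The SD sweep and the ARI-vs-gene-count curves cluster on nested gene sets,
so squared sample distances are accumulated blockwise (Gram updates) over
the ranked genes rather than recomputed — this is what keeps the
40-replicate × 100-point sweep under ~10 s.

Subsampling designs draw fixed per-subtype counts with replacement
(balanced 50/50, skewed 25/75 by default; the 25 always comes from the
first label level in synthetic data — with real data the caller labels
which subtype is rarer). Bootstrap duplicates are kept as distinct,
suffixed samples. Scores are recomputed inside every replicate. Pairwise
method comparisons use the one-sample t-test on the paired per-replicate
differences, unadjusted across pairs. Curve grids are ~1000 evenly spaced
integer counts from 2 to the post-filter total, deduplicated, smoothed
with a centered, edge-truncated running mean (window 100 grid points at
full scale).

## Problem sizes used by the committed runs

The acceptance script runs the Gaussian study at full scale (40 × 10,000 ×
100; ~5 s). The analysis drivers use NB cohorts of 6,000 genes (benchmark)
and 2,000 genes with 30 bootstrap datasets (detailed evaluation), chosen so
the complete study narrative reruns in minutes on one CPU; selection
quality, not dataset scale, is what the comparisons measure. The test
suite's property checks run on scaled-down replicas of each design plus a
fixed 6-gene × 10-sample fixture for exact oracle equivalence.

## Known limitations

- The dip's advantage for weakly shifted mixtures is marginal by nature: a
  one-SD mean shift leaves the mixture unimodal, so DIP sees only the
  flattened shape; its informative-gene ranking beats chance in aggregate
  but not in every replicate.
- Perfect label recovery on informative-only clustering is a
  high-probability event, not a certainty; roughly one replicate in a few
  hundred flips a single borderline sample.
- Wald NB p-values are mildly anticonservative at small n (observed ~0.058
  at the 0.05 level with 100 samples), an expected property of unshrunken
  ML dispersions.
- Ward on the correlation distance has no ESS interpretation; it is
  provided for parity, not recommended.
- The NB generator applies the fold change to group B in one direction;
  mixed up/down regulation can be composed by concatenating two generated
  blocks if needed.
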