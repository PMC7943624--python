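"""Score correctness: oracle equivalence, worked examples, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

import oracles
from featclust import (
    ScoreTable,
    bimodality_coefficient,
    fit_bimodal_mixture,
    bimodality_index,
    random_selection,
    score_coexpression,
    score_entropy,
    score_location,
    score_matrix,
    score_mvrs,
    score_spread,
    select_top,
    variance_reduction,
    best_univariate_split,
)
from featclust.dip import dip_statistic

RTOL = 1e-10


def _grid_starts_like_implementation(x):
    """The implementation's 10 quantile-split EM starts, recomputed here."""
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    starts = []
    for k in range(1, 11):
        frac = k / 11.0
        cut = min(max(int(round(frac * n)), 1), n - 1)
        lo, hi = xs[:cut], xs[cut:]
        var = (((lo - lo.mean()) ** 2).sum()
               + ((hi - hi.mean()) ** 2).sum()) / n
        starts.append((frac, lo.mean(), hi.mean(), math.sqrt(var)))
    return starts


class TestOracleEquivalence:
    """Every score on the fixed 6x10 fixture vs straight-from-formula math."""

    def test_location_and_spread(self, fixture_matrix):
        for gene, row in fixture_matrix.iterrows():
            x = row.to_list()
            assert score_location(fixture_matrix, "mean").scores[gene] == \
                pytest.approx(oracles.mean_oracle(x), rel=RTOL)
            assert score_location(fixture_matrix, "q3").scores[gene] == \
                pytest.approx(oracles.quantile_type7(x, 0.75), rel=RTOL)
            assert score_spread(fixture_matrix, "sd").scores[gene] == \
                pytest.approx(oracles.sd_oracle(x), rel=RTOL)
            assert score_spread(fixture_matrix, "iqr").scores[gene] == \
                pytest.approx(oracles.iqr_oracle(x), rel=RTOL)

    def test_entropy(self, fixture_matrix):
        ent = score_entropy(fixture_matrix).scores
        for gene, row in fixture_matrix.iterrows():
            assert ent[gene] == pytest.approx(
                oracles.entropy_oracle(row.to_list()), rel=RTOL
            )

    def test_coexpression(self, fixture_matrix):
        coex1 = score_coexpression(fixture_matrix, "coex1").scores.to_numpy()
        coex2 = score_coexpression(fixture_matrix, "coex2").scores.to_numpy()
        ref1, ref2 = oracles.coexpression_oracle(fixture_matrix.to_numpy())
        np.testing.assert_allclose(coex1, ref1, rtol=RTOL)
        np.testing.assert_allclose(coex2, ref2, rtol=RTOL)

    def test_dip_statistic_vs_lp(self, fixture_matrix):
        for _, row in fixture_matrix.iterrows():
            assert dip_statistic(row.to_numpy()) == pytest.approx(
                oracles.dip_lp_oracle(row.to_numpy()), abs=1e-9
            )

    def test_bimodality_index_grid(self, fixture_matrix):
        bi = score_matrix(fixture_matrix, "bi").scores
        for gene, row in fixture_matrix.iterrows():
            ref = oracles.bi_oracle(
                row.to_list(), _grid_starts_like_implementation(row)
            )
            assert bi[gene] == pytest.approx(ref, rel=1e-8, abs=1e-10)

    def test_vrs_wvrs_exhaustive(self, fixture_matrix):
        vrs = score_matrix(fixture_matrix, "vrs").scores
        wvrs = score_matrix(fixture_matrix, "wvrs").scores
        for gene, row in fixture_matrix.iterrows():
            x = row.to_list()
            in_a = oracles.best_split_exhaustive(x)
            assert vrs[gene] == pytest.approx(
                oracles.vrs_oracle(x, in_a), rel=RTOL
            )
            assert wvrs[gene] == pytest.approx(
                oracles.wvrs_oracle(x, in_a), rel=RTOL
            )

    def test_mvrs_fuzzy_loop(self, fixture_matrix):
        mvrs = score_matrix(fixture_matrix, "mvrs").scores
        for gene, row in fixture_matrix.iterrows():
            x = row.to_numpy()
            lower = best_univariate_split(x)
            ref = oracles.mvrs_oracle(
                x, x[lower].mean(), x[~lower].mean()
            )
            assert mvrs[gene] == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_bimodality_coefficient(self, fixture_matrix):
        bc = score_matrix(fixture_matrix, "bc").scores
        for gene, row in fixture_matrix.iterrows():
            assert bc[gene] == pytest.approx(
                oracles.bc_oracle(row.to_list()), rel=RTOL
            )


class TestWorkedExamples:
    def test_mean_and_q3_small_vectors(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]])
        assert score_location(m, "mean").scores.iloc[0] == 2.0
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]])
        assert score_location(m, "q3").scores.iloc[0] == pytest.approx(3.25)

    def test_constant_gene_location(self):
        m = pd.DataFrame([[7.0] * 5])
        assert score_location(m, "mean").scores.iloc[0] == 7.0
        assert score_location(m, "q3").scores.iloc[0] == 7.0

    def test_sd_hand_value_and_constant(self):
        m = pd.DataFrame([[0.0, 0.0, 1.0, 1.0], [3.0] * 4])
        sd = score_spread(m, "sd").scores
        assert sd.iloc[0] == pytest.approx(math.sqrt(1.0 / 3.0))
        assert sd.iloc[1] == 0.0
        assert score_spread(m, "iqr").scores.iloc[1] == 0.0

    def test_entropy_all_gaps_within_bandwidth(self):
        # all pairwise gaps <= h: sum K = n(n-1)/4, so ENT = log(2h).
        # Silverman's h never covers the full range, so widen the factor.
        from featclust.scores import EntropyConfig
        x = np.array([0.0, 1.0, 2.0])
        cfg = EntropyConfig(bandwidth_factor=10.0)
        h = 10.0 * np.std(x, ddof=1) * 3 ** (-0.2)
        assert h > np.ptp(x)
        ent = score_entropy(pd.DataFrame([x]), cfg).scores.iloc[0]
        assert ent == pytest.approx(math.log(2 * h), rel=1e-12)

    def test_entropy_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        c = 3.7
        e1 = score_entropy(pd.DataFrame([x])).scores.iloc[0]
        e2 = score_entropy(pd.DataFrame([c * x])).scores.iloc[0]
        assert e2 - e1 == pytest.approx(math.log(c), rel=1e-9)

    def test_entropy_constant_gene_is_nan(self):
        assert np.isnan(score_entropy(pd.DataFrame([[1.0] * 6])).scores.iloc[0])

    def test_coexpression_identical_and_reversed_ranks(self):
        base = np.arange(8.0)
        m = pd.DataFrame([base, 2 * base + 1, base[::-1].copy()])
        c1 = score_coexpression(m, "coex1").scores
        assert np.allclose(c1, 1.0)  # |rho| = 1 for all pairs
        m2 = pd.DataFrame([base, base**2 + 1])  # strictly monotone pair
        assert score_coexpression(m2, "coex2").scores.iloc[0] == \
            pytest.approx(1.0)

    def test_coexpression_constant_gene(self):
        m = pd.DataFrame([np.arange(6.0), np.ones(6), np.arange(6.0)[::-1]])
        tab = score_coexpression(m, "coex1")
        assert np.isnan(tab.scores.iloc[1])
        assert tab.scores.iloc[0] == pytest.approx(0.5)  # median of {1, 0}

    def test_bimodality_index_formula_cases(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        fit = fit_bimodal_mixture(x, starts="kmeans_single")
        # mu_a == mu_b forces BI = 0 regardless of p
        from featclust.mixture import MixtureFit
        degenerate = MixtureFit(p=0.3, mu_a=1.0, mu_b=1.0, sigma=2.0,
                                loglik=0.0, converged=True)
        assert bimodality_index(degenerate) == 0.0
        assert bimodality_index(fit) >= 0.0
        assert bimodality_index(fit, sqrt_fraction=True) >= \
            bimodality_index(fit)

    def test_bi_parameter_recovery(self):
        """EM recovers p and the mode separation of 0.5 N(0,1) + 0.5 N(4,1)."""
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(4, 1, 250)])
        fit = fit_bimodal_mixture(x, starts="grid")
        p_low = min(fit.p, 1 - fit.p)
        assert abs(p_low - 0.5) < 0.1
        assert abs(abs(fit.mu_a - fit.mu_b) - 4.0) < 0.5

    def test_vrs_clean_split_and_single_group(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert variance_reduction(x, "vrs") == pytest.approx(0.0, abs=1e-15)
        assert variance_reduction(x, "wvrs") == pytest.approx(0.0, abs=1e-15)
        one_group = variance_reduction(
            x, "vrs", partitioner=lambda v: np.zeros(len(v), dtype=int)
        )
        assert one_group == 1.0

    def test_wvrs_equals_vrs_for_balanced_split(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = np.sort(rng.normal(size=12))
            half = np.zeros(12, dtype=bool)
            half[:6] = True
            part = lambda v, m=half: m
            assert variance_reduction(x, "wvrs", partitioner=part) == \
                pytest.approx(variance_reduction(x, "vrs", partitioner=part))

    def test_mvrs_separated_clusters(self):
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        assert score_mvrs(x) < variance_reduction(x, "vrs") + 0.05
        assert score_mvrs(x) < 0.05

    def test_mvrs_unimodal_vs_bimodal(self):
        rng = np.random.default_rng(9)
        uni = rng.normal(0, 1, 200)
        bim = np.concatenate([rng.normal(-2, 1, 100), rng.normal(2, 1, 100)])
        assert score_mvrs(uni) > score_mvrs(bim)

    def test_mvrs_memberships_sum_to_one(self):
        from featclust.vrs import _fcm_batch
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 20))
        u, _ = _fcm_batch(x, np.array([[-1.0, 1.0]] * 3))
        np.testing.assert_allclose(u.sum(axis=2), 1.0, rtol=1e-12)

    def test_bc_limits(self):
        # balanced two-point mass: skew -> 0, excess kurtosis -> -2, BC -> 1
        x = np.array([0.0, 1.0] * 200)
        assert bimodality_coefficient(x) == pytest.approx(1.0, abs=0.02)
        # large-sample normal-like moments: BC ~ 1/3
        rng = np.random.default_rng(1)
        z = rng.normal(size=20000)
        assert bimodality_coefficient(z) == pytest.approx(1.0 / 3.0, abs=0.03)
        assert np.isnan(bimodality_coefficient(np.ones(10)))


class TestSelection:
    def test_select_top_directions_and_ties(self):
        t = ScoreTable("demo", pd.Series([3.0, 1.0, 2.0],
                                         index=["a", "b", "c"]), "higher")
        assert list(select_top(t, 2)) == ["a", "c"]
        tied = ScoreTable("demo", pd.Series([1.0, 1.0, 1.0],
                                            index=["a", "b", "c"]), "higher")
        assert list(select_top(tied, 2)) == ["a", "b"]
        lower = ScoreTable("demo", pd.Series([3.0, 1.0, 2.0],
                                             index=["a", "b", "c"]), "lower")
        assert list(select_top(lower, 2)) == ["b", "c"]

    def test_select_top_excludes_nan_and_errors(self):
        t = ScoreTable("demo", pd.Series([1.0, np.nan, 0.5],
                                         index=["a", "b", "c"]), "higher")
        assert list(select_top(t, 2)) == ["a", "c"]
        with pytest.raises(ValueError, match="demo"):
            select_top(t, 3)

    def test_tiebreak_orders_equal_primaries(self):
        t = ScoreTable(
            "demo",
            pd.Series([0.5, 0.5, 0.1], index=["a", "b", "c"]),
            "lower",
            tiebreak=pd.Series([1.0, 2.0, 0.0], index=["a", "b", "c"]),
        )
        assert list(select_top(t, 3)) == ["c", "b", "a"]

    def test_random_selection_properties(self):
        ids = [f"g{i}" for i in range(20)]
        sel = random_selection(ids, 20, seed=3)
        assert sorted(sel) == sorted(ids)
        assert list(random_selection(ids, 5, seed=7)) == \
            list(random_selection(ids, 5, seed=7))
        with pytest.raises(ValueError):
            random_selection(ids, 21, seed=0)

    def test_random_selection_frequencies(self):
        ids = list(range(40))
        counts = np.zeros(40)
        for rep in range(1000):
            for g in random_selection(ids, 10, seed=rep):
                counts[g] += 1
        freq = counts / 1000
        # binomial(1000, 0.25): SD ~ 0.0137, allow 5 SD
        assert np.all(np.abs(freq - 0.25) < 0.07)


@pytest.fixture(scope="module")
def matrix():
    rng = np.random.default_rng(77)
    rows = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 30)
            for _ in range(7)]
    rows.append(np.concatenate([rng.normal(-3, 0.5, 15),
                                rng.normal(3, 0.5, 15)]))
    return pd.DataFrame(np.array(rows))


class TestInvariances:
    """Permutation/shift/scale behaviour of every method on one matrix."""

    @pytest.mark.parametrize("method", [
        "m", "q3", "sd", "iqr", "ent", "coex1", "coex2",
        "dip", "bi", "vrs", "wvrs", "mvrs", "bc",
    ])
    def test_sample_permutation_invariance(self, matrix, method):
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.shape[1])
        a = score_matrix(matrix, method).scores.to_numpy()
        b = score_matrix(matrix.iloc[:, perm], method).scores.to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("method,kind", [
        ("m", "shift_equivariant"), ("q3", "shift_equivariant"),
        ("sd", "shift_invariant"), ("iqr", "shift_invariant"),
        ("vrs", "affine_invariant"), ("wvrs", "affine_invariant"),
        ("mvrs", "affine_invariant"), ("bc", "affine_invariant"),
        ("bi", "shift_invariant"),
    ])
    def test_shift_scale_behaviour(self, matrix, method, kind):
        shift, scale = 11.5, 2.5
        base = score_matrix(matrix, method).scores.to_numpy()
        shifted = score_matrix(matrix + shift, method).scores.to_numpy()
        if kind == "shift_equivariant":
            np.testing.assert_allclose(shifted, base + shift, rtol=1e-9)
            return
        np.testing.assert_allclose(shifted, base, rtol=1e-7, atol=1e-9)
        if kind == "affine_invariant":
            scaled = score_matrix(matrix * scale, method).scores.to_numpy()
            np.testing.assert_allclose(scaled, base, rtol=1e-7, atol=1e-9)

    @pytest.mark.parametrize("method", ["sd", "iqr"])
    def test_spread_scale_equivariance(self, matrix, method):
        scale = 2.5
        base = score_matrix(matrix, method).scores.to_numpy()
        scaled = score_matrix(matrix * scale, method).scores.to_numpy()
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-10)

    def test_coexpression_gene_permutation(self, matrix):
        rng = np.random.default_rng(2)
        perm = rng.permutation(matrix.shape[0])
        for variant in ("coex1", "coex2"):
            a = score_matrix(matrix, variant).scores.to_numpy()
            b = score_matrix(matrix.iloc[perm], variant).scores.to_numpy()
            np.testing.assert_allclose(a[perm], b, rtol=1e-9)

    def test_score_ranges(self, matrix):
        vrs = score_matrix(matrix, "vrs").scores
        assert ((vrs >= 0) & (vrs <= 1)).all()
        assert (score_matrix(matrix, "wvrs").scores >= 0).all()
        bc = score_matrix(matrix, "bc").scores
        assert ((bc > 0) & (bc <= 1)).all()


def test_informative_genes_rank_well_on_gaussian(small_gaussian):
    """SD/IQR/ENT/BI rank truly informative genes above mid-pack."""
    ds = small_gaussian
    n = ds.n_genes
    for method in ("sd", "iqr", "ent", "bi"):
        table = score_matrix(ds.matrix, method)
        ranking = list(table.ranking())
        pos = [ranking.index(g) for g in ds.informative_genes]
        assert np.mean(pos) < n / 2, method


def test_dip_ranks_informative_genes_in_aggregate():
    """DIP's edge at a 1-SD shift is weak (the mixture stays unimodal, only
    its flattened shape is detectable), so the mean rank of informative
    genes beats mid-pack in aggregate over replicates at the study's
    sample size, not necessarily in every replicate."""
    from featclust import GaussianSimConfig, simulate_gaussian_two_group
    fractions = []
    for seed in range(11, 16):
        ds = simulate_gaussian_two_group(GaussianSimConfig(
            n_per_group=50, n_features=1000, n_informative=50, seed=seed))
        ranking = list(score_matrix(ds.matrix, "dip").ranking())
        pos = [ranking.index(g) for g in ds.informative_genes]
        fractions.append(np.mean(pos) / ds.n_genes)
    assert np.mean(fractions) < 0.5
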