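import numpy as np
import pytest
from scipy import stats

from raretest.assoc_unrelated import lrt_linear, permutation_p, zscore_simple
from raretest.assoc_unrelated import test_cast as cast_test
from raretest.assoc_unrelated import test_cmc as cmc_test
from raretest.assoc_unrelated import test_sm as sm_test
from raretest.assoc_unrelated import test_vt as vt_test
from raretest.assoc_unrelated import test_ws as ws_test
from raretest.core_types import GenotypeMatrix, GeneSet
from raretest.simdata import SimConfig, simulate_genotypes, simulate_phenotype

from conftest import ols_loglik


def _matrix(counts, prefix="v"):
    counts = np.asarray(counts, dtype=float)
    return GenotypeMatrix(
        [f"S{i}" for i in range(counts.shape[0])],
        [f"{prefix}{j}" for j in range(counts.shape[1])],
        counts,
    )


@pytest.fixture(scope="module")
def null_data():
    cfg = SimConfig(n_samples=80, variants_per_gene=10, maf_range=(0.01, 0.2), seed=42)
    ds = simulate_genotypes(cfg)
    y = simulate_phenotype(ds, cfg, 0).values
    return ds, y


class TestLrtLinear:
    def test_matches_closed_form_oracle(self, rng):
        n = 20
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        res = lrt_linear(y, x[:, None], df=1)
        expected = 2 * (
            ols_loglik(y, np.column_stack([np.ones(n), x]))
            - ols_loglik(y, np.ones((n, 1)))
        )
        assert res.statistic == pytest.approx(expected, abs=1e-8)
        assert res.p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-10)

    def test_multicolumn_matches_oracle(self, rng):
        n, k = 40, 3
        X = rng.standard_normal((n, k))
        y = X @ [0.3, -0.2, 0.0] + rng.standard_normal(n)
        res = lrt_linear(y, X, df=k)
        expected = 2 * (
            ols_loglik(y, np.column_stack([np.ones(n), X]))
            - ols_loglik(y, np.ones((n, 1)))
        )
        assert res.df == k
        assert res.statistic == pytest.approx(expected, abs=1e-8)

    def test_constant_phenotype_gives_zero_statistic(self, rng):
        y = np.full(30, 1.7)
        res = lrt_linear(y, rng.standard_normal(30)[:, None], df=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_exact_linear_fit_capped_not_infinite(self, rng):
        x = rng.standard_normal(25)
        res = lrt_linear(2.0 * x + 1.0, x[:, None], df=1)
        assert np.isfinite(res.statistic)
        assert res.p < 1e-10

    def test_constant_predictor_is_na(self):
        res = lrt_linear(np.arange(10.0), np.ones((10, 1)), df=1)
        assert res.status == "n/a"

    def test_aliased_column_reduces_df(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(UserWarning, match="aliased"):
            res = lrt_linear(rng.standard_normal(30), X, df=2)
        assert res.df == 1

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        y = 0.3 * x + rng.standard_normal(50)
        base = lrt_linear(y, x[:, None], df=1).statistic
        scaled = lrt_linear(-3.2 * y + 7.0, x[:, None], df=1).statistic
        assert scaled == pytest.approx(base, rel=1e-9)


class TestCast:
    def test_single_rare_variant_ca_equals_cp(self, null_data):
        # gene with one variant: CA and CP collapse to the same indicator
        ds, y = null_data
        v = ds.geneset["GENE1"][0]
        gs = GeneSet({"G": [v]}, ds.matrix)
        ca = cast_test(y, ds.matrix, gs, "G", "CA", 0.5)
        cp = cast_test(y, ds.matrix, gs, "G", "CP", 0.5)
        assert ca.statistic == pytest.approx(cp.statistic, abs=1e-12)

    def test_method_labels(self, null_data):
        ds, y = null_data
        assert cast_test(y, ds.matrix, ds.geneset, "GENE1", "CA", 0.01).method == "CA1"
        assert cast_test(y, ds.matrix, ds.geneset, "GENE1", "CP", 0.05).method == "CP5"

    def test_empty_eligible_set_is_na(self):
        m = _matrix(np.zeros((20, 3)))
        gs = GeneSet({"G": ["v0", "v1", "v2"]}, m)
        res = cast_test(np.random.default_rng(0).standard_normal(20), m, gs, "G", "CA", 0.05)
        assert res.status == "n/a"

    def test_null_pvalues_roughly_uniform(self):
        # permuting the phenotype against fixed genotypes: p ~ U(0,1)
        cfg = SimConfig(n_samples=100, variants_per_gene=10,
                        maf_range=(0.02, 0.05), seed=9)
        ds = simulate_genotypes(cfg)
        pvals = [
            cast_test(simulate_phenotype(ds, cfg, rep).values, ds.matrix,
                      ds.geneset, "GENE1", "CP", 0.05).p
            for rep in range(300)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCmc:
    def test_cmc1_reduces_to_ca1_without_midfrequency_variants(self, rng):
        counts = rng.binomial(2, 0.004, size=(400, 6))  # all mafs < 1%
        m = _matrix(counts)
        gs = GeneSet({"G": m.variants}, m)
        y = rng.standard_normal(400)
        cmc1 = cmc_test(y, m, gs, "G", "CMC1")
        ca1 = cast_test(y, m, gs, "G", "CA", 0.01)
        assert cmc1.df == 1
        assert cmc1.statistic == pytest.approx(ca1.statistic, abs=1e-9)

    def test_cmc2_without_rare_group_is_bivariate(self, rng):
        counts = rng.binomial(2, 0.03, size=(400, 2))  # both mafs in 1-5%
        m = _matrix(counts)
        gs = GeneSet({"G": m.variants}, m)
        res = cmc_test(rng.standard_normal(400), m, gs, "G", "CMC2")
        assert res.df == 2

    def test_cmc3_matches_two_fit_oracle(self, rng):
        counts = np.column_stack(
            [rng.binomial(2, 0.004, 300), rng.binomial(2, 0.3, 300),
             rng.binomial(2, 0.15, 300)]
        )
        m = _matrix(counts)
        gs = GeneSet({"G": m.variants}, m)
        y = rng.standard_normal(300) + 0.2 * counts[:, 1]
        res = cmc_test(y, m, gs, "G", "CMC3")
        rare = (counts[:, 0] >= 1).astype(float)
        X = np.column_stack([np.ones(300), rare, counts[:, 1], counts[:, 2]])
        expected = 2 * (ols_loglik(y, X) - ols_loglik(y, np.ones((300, 1))))
        assert res.df == 3
        assert res.statistic == pytest.approx(expected, abs=1e-8)

    def test_cmc1_statistic_below_cmc2_on_nested_fixture(self, rng):
        # fixture with no homozygotes and no double carriers in the 1-5%
        # group, so the CMC1 collapsed column lies in the span of CMC2's
        # individual columns and the models are strictly nested
        counts = np.zeros((200, 3))
        counts[:2, 0] = 1  # maf 0.005 (<1%)
        counts[10:16, 1] = 1  # maf 0.015
        counts[20:28, 2] = 1  # maf 0.02
        m = _matrix(counts)
        gs = GeneSet({"G": m.variants}, m)
        y = np.random.default_rng(5).standard_normal(200) + 0.5 * counts[:, 1]
        c1 = cmc_test(y, m, gs, "G", "CMC1")
        c2 = cmc_test(y, m, gs, "G", "CMC2")
        assert c1.statistic <= c2.statistic + 1e-9

    def test_all_groups_empty_is_na(self, rng):
        counts = rng.binomial(2, 0.3, size=(100, 3))  # all common (>5%)
        m = _matrix(counts)
        gs = GeneSet({"G": m.variants}, m)
        res = cmc_test(rng.standard_normal(100), m, gs, "G", "CMC1")
        assert res.status == "n/a"


class TestSingleMarker:
    def test_single_variant_gene_p_equals_variant_p(self, rng):
        counts = rng.binomial(2, 0.1, size=(100, 1))
        m = _matrix(counts)
        gs = GeneSet({"G": ["v0"]}, m)
        y = rng.standard_normal(100)
        res = sm_test(y, m, gs, "G")
        single = lrt_linear(y, counts.astype(float), df=1)
        assert res.p == pytest.approx(single.p, abs=1e-12)

    def test_max_statistic_is_min_p_variant(self, null_data):
        ds, y = null_data
        sub = ds.matrix.subset(variants=ds.geneset["GENE1"])
        from raretest.core_types import maf_array

        mafs = maf_array(sub)
        stats_j = [
            lrt_linear(y, sub.counts[:, [j]], df=1).statistic
            for j in np.flatnonzero(mafs > 0)
        ]
        res = sm_test(y, ds.matrix, ds.geneset, "GENE1")
        assert res.statistic == pytest.approx(max(stats_j), abs=1e-10)

    def test_bonferroni_scaling(self, null_data):
        ds, y = null_data
        sub = ds.matrix.subset(variants=ds.geneset["GENE1"])
        from raretest.core_types import maf_array

        mafs = maf_array(sub)
        j_g = int((mafs > 0).sum())
        p_j = [
            lrt_linear(y, sub.counts[:, [j]], df=1).p
            for j in np.flatnonzero(mafs > 0)
        ]
        res = sm_test(y, ds.matrix, ds.geneset, "GENE1")
        assert res.p == pytest.approx(min(1.0, j_g * min(p_j)), abs=1e-12)


class TestPermutation:
    def test_addone_bounds(self):
        y = np.random.default_rng(0).standard_normal(40)
        # observed above every permuted statistic -> smallest attainable p
        p_min = permutation_p(1.0, lambda yp: 0.0, y, 1000, seed=1)
        assert p_min == pytest.approx(1 / 1001)
        # observed below every permuted statistic -> p = 1
        p_max = permutation_p(-1.0, lambda yp: 0.0, y, 100, seed=1)
        assert p_max == pytest.approx(1.0)

    def test_reproducible_under_fixed_seed(self, null_data):
        ds, y = null_data
        a = ws_test(y, ds.matrix, ds.geneset, "GENE1", 200, seed=7)
        b = ws_test(y, ds.matrix, ds.geneset, "GENE1", 200, seed=7)
        assert a.p == b.p

    def test_doubling_b_stays_within_monte_carlo_error(self, null_data):
        ds, y = null_data
        p1 = ws_test(y, ds.matrix, ds.geneset, "GENE1", 500, seed=3).p
        p2 = ws_test(y, ds.matrix, ds.geneset, "GENE1", 1000, seed=4).p
        se = np.sqrt(p1 * (1 - p1) / 500 + p2 * (1 - p2) / 1000)
        assert abs(p1 - p2) < 4 * se + 1e-3


class TestVt:
    def test_zmax_dominates_each_threshold(self, null_data):
        ds, y = null_data
        from raretest.collapsing import collapse_cp, vt_thresholds
        from raretest.core_types import maf_array

        sub = ds.matrix.subset(variants=ds.geneset["GENE1"])
        mafs = maf_array(sub)
        res = vt_test(y, ds.matrix, ds.geneset, "GENE1", 50, seed=0)
        for t in vt_thresholds(sub, mafs=mafs):
            z = abs(zscore_simple(y, collapse_cp(sub, float(t), mafs=mafs).values))
            assert res.statistic >= z - 1e-10

    def test_single_threshold_equals_cp_zscore(self, rng):
        counts = rng.binomial(2, 0.05, size=(100, 3))
        m = _matrix(counts)
        gs = GeneSet({"G": m.variants}, m)
        # force all mafs equal by construction: copy one column
        counts[:, 1] = counts[:, 0]
        counts[:, 2] = counts[:, 0]
        m = _matrix(counts)
        gs = GeneSet({"G": m.variants}, m)
        y = rng.standard_normal(100)
        from raretest.collapsing import collapse_cp

        res = vt_test(y, m, gs, "G", 100, seed=2)
        z = abs(zscore_simple(y, collapse_cp(m, 0.5).values))
        assert res.statistic == pytest.approx(z, abs=1e-12)


class TestWs:
    def test_statistic_is_burden_zscore(self, null_data):
        ds, y = null_data
        from raretest.collapsing import collapse_ws, ws_weights

        sub = ds.matrix.subset(variants=ds.geneset["GENE1"])
        c = collapse_ws(sub, ws_weights(sub)).values
        res = ws_test(y, ds.matrix, ds.geneset, "GENE1", 50, seed=0)
        assert res.statistic == pytest.approx(abs(zscore_simple(y, c)), abs=1e-12)

    def test_rare_burden_beats_ca1_with_aligned_effects(self):
        # all variants causal in one direction, no common noise variants:
        # the frequency-weighted burden should reject at least as often
        cfg = SimConfig(n_samples=300, variants_per_gene=8,
                        maf_range=(0.005, 0.03),
                        causal_effects={"GENE1": 0.45}, causal_t_maf=0.5, seed=21)
        ds = simulate_genotypes(cfg)
        ws_hits = ca_hits = 0
        for rep in range(40):
            y = simulate_phenotype(ds, cfg, rep).values
            ws_hits += ws_test(y, ds.matrix, ds.geneset, "GENE1", 300,
                               seed=[rep]).p <= 0.05
            ca_hits += cast_test(y, ds.matrix, ds.geneset, "GENE1", "CA", 0.01).p <= 0.05
        assert ws_hits >= ca_hits
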