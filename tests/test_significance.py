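import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctpathway.profiles import DEVector
from ctpathway.propagation import RwrParams, multi_rwr
from ctpathway.scoring import compute_pathway_scores, compute_risk_scores
from ctpathway.significance import (
    assess_significance,
    bh_fdr,
    empirical_pvalue,
    gpd_refine,
    permutation_null,
    permute_profile,
)

UNTRUNC = RwrParams(epsilon=0)


class TestPermuteProfile:
    def test_single_gene_identity(self):
        de = DEVector(genes=["A"], values=np.array([0.4]))
        assert permute_profile(de, 0).values == pytest.approx([0.4])

    def test_multiset_preserved(self):
        de = DEVector(genes=list("ABCDE"), values=np.arange(5.0))
        out = permute_profile(de, 123)
        assert sorted(out.values) == pytest.approx(sorted(de.values))
        assert out.genes == de.genes

    def test_seed_determinism(self):
        de = DEVector(genes=list("ABCDEFGH"), values=np.arange(8.0))
        a = permute_profile(de, 99).values
        b = permute_profile(de, 99).values
        assert a == pytest.approx(b)


@pytest.fixture(scope="module")
def world(request):
    from ctpathway.fixtures import FixtureSpec, make_network, make_pathways, make_profile
    from ctpathway.profiles import build_de_vector

    spec = FixtureSpec(n_genes=200, n_pathways=25, size_range=(5, 12), seed=21)
    g = make_network(spec)
    pws = make_pathways(g, spec)
    prof = make_profile(g, pws, spec)
    de = build_de_vector(prof, g)
    C = multi_rwr(g, de.genes, UNTRUNC)
    return g, pws, de, C


class TestPermutationNull:
    def test_constant_de_null_equals_real(self, world):
        g, pws, de, C = world
        const = DEVector(genes=de.genes, values=np.full(de.L, 0.3))
        rs = compute_risk_scores(C, const)
        scores = compute_pathway_scores(rs, pws, g)
        null = permutation_null(C, const, pws, g, h=20, rng_seed=0)
        for s, nulls in zip(scores, null.ps_random):
            assert nulls == pytest.approx(np.full(20, s.ps), abs=1e-12)

    def test_h_one(self, world):
        g, pws, de, C = world
        null = permutation_null(C, de, pws, g, h=1, rng_seed=0)
        assert null.ps_random.shape[1] == 1

    def test_null_mean_matches_mean_de(self, world):
        # by linearity, E[PS_perm] = PS evaluated at the constant mean-DE vector
        g, pws, de, C = world
        null = permutation_null(C, de, pws, g, h=2000, rng_seed=5)
        const = DEVector(genes=de.genes, values=np.full(de.L, de.values.mean()))
        rs = compute_risk_scores(C, const)
        expected = np.array([s.ps for s in compute_pathway_scores(rs, pws, g)])
        got = null.ps_random.mean(axis=1)
        assert got == pytest.approx(expected, rel=0.05)

    def test_extending_h_keeps_prefix(self, world):
        g, pws, de, C = world
        a = permutation_null(C, de, pws, g, h=10, rng_seed=7).ps_random
        b = permutation_null(C, de, pws, g, h=25, rng_seed=7).ps_random
        assert a == pytest.approx(b[:, :10])

    def test_reuses_c_bit_identically(self, world):
        g, pws, de, C = world
        a = permutation_null(C, de, pws, g, h=5, rng_seed=3).ps_random
        C2 = multi_rwr(g, de.genes, UNTRUNC)  # recomputed crosstalk, same DE-free values
        b = permutation_null(C2, de, pws, g, h=5, rng_seed=3).ps_random
        assert np.array_equal(a, b)


class TestEmpiricalP:
    def test_all_below(self):
        assert empirical_pvalue(5.0, np.arange(10.0) / 10) == 0.0

    def test_all_ties(self):
        assert empirical_pvalue(1.0, np.ones(10)) == 1.0

    def test_median(self):
        rng = np.random.default_rng(0)
        nulls = rng.normal(size=1000)
        med = np.median(nulls)
        assert empirical_pvalue(med, nulls) == pytest.approx(0.5, abs=0.01)

    def test_h_mismatch(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.ones(10), h=5)


class TestGpdRefine:
    def test_below_threshold_returns_empirical(self):
        rng = np.random.default_rng(1)
        nulls = rng.exponential(1.0, 1000)
        med = float(np.median(nulls))
        assert gpd_refine(med, nulls) == empirical_pvalue(med, nulls)

    def test_bounded_by_tail_fraction(self):
        rng = np.random.default_rng(2)
        nulls = rng.exponential(1.0, 1000)
        ps = float(nulls.max() + 1.0)
        assert gpd_refine(ps, nulls, n_exceed=250) <= 250 / 1000

    def test_degenerate_tail_fallback(self, caplog):
        nulls = np.concatenate([np.zeros(500), np.ones(500)])
        with caplog.at_level("WARNING"):
            p = gpd_refine(2.0, nulls, n_exceed=250)
        assert p == pytest.approx(1 / 1001)

    def test_tiny_null(self):
        assert gpd_refine(1.0, np.array([0.5])) == pytest.approx(1 / 2)


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_single(self):
        assert bh_fdr([0.7]) == pytest.approx([0.7])

    def test_cap_at_one(self):
        assert bh_fdr([0.9, 0.95, 1.0]).max() <= 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_order_invariance(self, p):
        fwd = bh_fdr(p)
        rev = bh_fdr(p[::-1])[::-1]
        assert fwd == pytest.approx(rev, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p_rank(self, p):
        p_arr = np.asarray(p)
        fdr = bh_fdr(p_arr)
        order = np.argsort(p_arr, kind="stable")
        assert np.all(np.diff(fdr[order]) >= -1e-12)


class TestAssess:
    def test_end_to_end_sorting_and_flags(self, world):
        g, pws, de, C = world
        rs = compute_risk_scores(C, de)
        scores = compute_pathway_scores(rs, pws, g)
        null = permutation_null(C, de, pws, g, h=200, rng_seed=0)
        results = assess_significance(scores, null, fdr_threshold=0.5)
        fdrs = [r.fdr for r in results]
        assert fdrs == sorted(fdrs)
        for r in results:
            assert 0 <= r.p_final <= 1
            assert r.significant == (r.fdr < 0.5)

    def test_refinement_only_below_floor(self, world):
        g, pws, de, C = world
        rs = compute_risk_scores(C, de)
        scores = compute_pathway_scores(rs, pws, g)
        null = permutation_null(C, de, pws, g, h=200, rng_seed=0)
        results = assess_significance(scores, null, exceed_floor=10)
        for r in results:
            if r.p_empirical >= 10 / 200:
                assert r.p_final == r.p_empirical
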