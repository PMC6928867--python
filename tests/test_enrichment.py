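"""Exact over-representation statistics against independent oracles.

Oracles: literal enumeration of all C(N, n) draws (tiny N), exact rational
arithmetic over the hypergeometric support, and scipy's survival function —
all independent of the log-space implementation under test.
"""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom
from statsmodels.stats.multitest import multipletests

import cordhox as cx


def tail_by_draw_enumeration(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by enumerating every n-subset of an N-element universe."""
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(marked.intersection(draw)) >= k)
    return Fraction(hits, math.comb(N, n))


def tail_by_exact_sum(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) as an exact rational sum over the support."""
    return sum(
        (Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
         for i in range(k, min(n, K) + 1)),
        Fraction(0))


class TestHypergeomTail:
    def test_published_contingency(self):
        # 2 module TFs among 7 partners, 12 module TFs in a 1211-TF catalog
        p = cx.hypergeom_tail(1211, 12, 7, 2)
        assert p == pytest.approx(0.0018, abs=2e-4)
        assert round(p, 3) == 0.002

    def test_k_zero_is_one(self):
        assert cx.hypergeom_tail(100, 10, 5, 0) == 1.0

    def test_small_case_matches_draw_enumeration(self):
        expected = tail_by_draw_enumeration(10, 5, 4, 2)
        assert expected == Fraction(155, 210)
        assert cx.hypergeom_tail(10, 5, 4, 2) == pytest.approx(float(expected), rel=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [
        (8, 3, 5, 1), (9, 9, 4, 4), (12, 6, 6, 3), (7, 2, 7, 2), (11, 0, 5, 0),
    ])
    def test_matches_draw_enumeration(self, N, K, n, k):
        assert cx.hypergeom_tail(N, K, n, k) == pytest.approx(
            float(tail_by_draw_enumeration(N, K, n, k)), rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_matches_scipy_sf_at_genome_scale(self, data):
        N = data.draw(st.integers(1000, 25000))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, min(N, 500)))
        k = data.draw(st.integers(0, min(n, K)))
        ours = cx.hypergeom_tail(N, K, n, k)
        theirs = float(scipy_hypergeom.sf(k - 1, N, K, n))
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-300)

    @pytest.mark.parametrize("N,K,n,k", [
        (10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (5, 3, 3, 4),
    ])
    def test_bound_violations_rejected(self, N, K, n, k):
        with pytest.raises(ValueError):
            cx.hypergeom_tail(N, K, n, k)

    def test_saturated_overlap_small_universes(self):
        # k = n = K, checked exhaustively against exact rational sums
        for N in range(1, 31):
            for K in range(N + 1):
                n = K
                assert cx.hypergeom_tail(N, K, n, K) == pytest.approx(
                    float(tail_by_exact_sum(N, K, n, K)), rel=1e-12)


class TestFoldEnrichment:
    def test_zero_iff_k_zero(self):
        assert cx.fold_enrichment(100, 10, 5, 0) == 0.0
        assert cx.fold_enrichment(100, 10, 5, 1) > 0.0

    @given(st.integers(1, 50), st.integers(1, 10))
    def test_scale_free_in_N_and_K(self, N, mult):
        K, n, k = max(1, N // 3), max(1, N // 4), 1
        base = cx.fold_enrichment(N, K, n, k)
        scaled = cx.fold_enrichment(N * mult, K * mult, n, k)
        assert scaled == pytest.approx(base)


class TestAdjustments:
    def test_bh_step_up_hand_example(self):
        assert cx.adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_bh_single_value_unchanged(self):
        assert cx.adjust_bh([0.3]) == [0.3]

    def test_bh_equal_ps_unchanged(self):
        assert cx.adjust_bh([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_bonferroni_multiplies_and_caps(self):
        assert cx.adjust_bonferroni([0.01] * 10) == pytest.approx([0.1] * 10)
        assert cx.adjust_bonferroni([0.2] + [0.001] * 9)[0] == 1.0
        assert cx.adjust_bonferroni([0.07]) == [0.07]

    @pytest.mark.parametrize("adjust", [cx.adjust_bh, cx.adjust_bonferroni])
    def test_out_of_range_rejected(self, adjust):
        with pytest.raises(ValueError):
            adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            adjust([1.5])

    @settings(deadline=None, max_examples=50)
    @given(p=st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=40))
    def test_bh_dominates_raw_and_matches_statsmodels(self, p):
        ours = cx.adjust_bh(p)
        assert all(q >= pi for q, pi in zip(ours, p))
        assert all(q <= 1.0 for q in ours)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @settings(deadline=None, max_examples=30)
    @given(p=st.lists(st.floats(1e-10, 1.0), min_size=2, max_size=20),
           seed=st.integers(0, 1000))
    def test_bh_permutation_equivariant(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        direct = np.asarray(cx.adjust_bh(p))[perm]
        permuted = np.asarray(cx.adjust_bh(list(np.asarray(p)[perm])))
        assert np.allclose(direct, permuted)


class TestOverrepresentation:
    def test_planted_homeobox_overlap(self):
        # 2 of 4 family genes drawn in a 2-gene query from a 100-gene universe
        universe = {f"G{i}" for i in range(96)} | {"HOXA5", "HOXB8", "HOXB2", "HOXD8"}
        lib = cx.GeneSetLibrary(entries={
            "HOMEOBOX": frozenset({"HOXA5", "HOXB8", "HOXB2", "HOXD8"})})
        rows = cx.overrepresentation({"HOXA5", "HOXB8"}, lib, universe)
        (row,) = rows
        assert (row.k, row.n, row.K, row.N) == (2, 2, 4, 100)
        assert row.p_raw == pytest.approx(6 / 4950, rel=1e-12)
        assert row.p_adj == row.p_raw  # single term

    def test_disjoint_term_scores_one(self, small_library):
        universe = {"HOXA5", "HOXB8", "HOXB2", "HOXD8", "GFAP", "AQP4", "X1"}
        rows = cx.overrepresentation({"X1"}, small_library, universe)
        assert all(r.p_raw == 1.0 and r.fold == 0.0 for r in rows if r.k == 0)

    def test_query_outside_universe_dropped_then_error_when_empty(self, small_library):
        with pytest.raises(ValueError, match="empty"):
            cx.overrepresentation({"NOT_THERE"}, small_library, {"HOXA5", "GFAP"})

    def test_rows_sorted_by_adjusted_p(self, small_library):
        universe = {"HOXA5", "HOXB8", "HOXB2", "HOXD8", "GFAP", "AQP4"}
        rows = cx.overrepresentation({"HOXA5", "HOXB8"}, small_library, universe)
        assert [r.p_adj for r in rows] == sorted(r.p_adj for r in rows)


class TestModuleEnrichment:
    def test_published_worked_example(self, interactome_bundle):
        row = cx.module_enrichment(cx.HOXA5_TF_PARTNERS,
                                   interactome_bundle.module_tfs,
                                   interactome_bundle.catalog)
        assert (row.k, row.n, row.K, row.N) == (2, 7, 12, 1211)
        assert row.p_raw == pytest.approx(0.0018, abs=2e-4)
        assert row.fold == pytest.approx((2 / 7) / (12 / 1211))

    def test_no_overlap_gives_p_one(self, interactome_bundle):
        partners = frozenset(list(interactome_bundle.catalog.members
                                  - interactome_bundle.module_tfs)[:5])
        row = cx.module_enrichment(partners, interactome_bundle.module_tfs,
                                   interactome_bundle.catalog)
        assert row.k == 0 and row.p_raw == 1.0

    def test_partners_equal_module_matches_exact_sum(self):
        cat = cx.TFCatalog(members=frozenset(f"T{i}" for i in range(20)))
        module = frozenset(list(cat.members)[:6])
        row = cx.module_enrichment(module, module, cat)
        assert row.p_raw == pytest.approx(
            float(tail_by_exact_sum(20, 6, 6, 6)), rel=1e-12)

    def test_empty_partner_set_rejected(self, interactome_bundle):
        with pytest.raises(ValueError):
            cx.module_enrichment(frozenset(), interactome_bundle.module_tfs,
                                 interactome_bundle.catalog)
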