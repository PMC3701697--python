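"""Fisher/EASE enrichment, smaller-of overlap rule, permutation calibration."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzactivity.matching import MatchMap, MatchRecord, TheoreticalIndex, build_derivative_table
from mzactivity.model_io import to_metabolite_graph
from mzactivity.pathways import (
    EnrichmentTable,
    build_null_pathway_pvalues,
    ease_score,
    enrich_pathways,
    fisher_right_tail,
    fit_pathway_null,
    overlap_count,
    pathway_significance,
)


def hypergeom_right_tail_exact(k, n, K, N):
    """Independent oracle: exact rational P(X >= k), X ~ Hypergeom(N, K, n)."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        if n - x <= N - K:
            acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def _match_map(pairs):
    """pairs: (feature_id, metabolite_id) tuples."""
    return MatchMap([MatchRecord(f, m, "M+H[1+]", 100.0, 0.1) for f, m in pairs])


class TestFisherAndEase:
    def test_hand_derived_instance(self):
        t = EnrichmentTable(k=3, n=5, K=5, N_tot=20)
        assert fisher_right_tail(t) == pytest.approx(1126 / 15504, rel=1e-12)
        assert ease_score(t) == pytest.approx(5676 / 15504, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert fisher_right_tail(EnrichmentTable(0, 5, 5, 20)) == pytest.approx(1.0)

    def test_category_equal_to_universe_is_certain(self):
        assert fisher_right_tail(EnrichmentTable(4, 4, 20, 20)) == pytest.approx(1.0)

    def test_ease_of_single_hit_is_one(self):
        assert ease_score(EnrichmentTable(1, 5, 5, 20)) == pytest.approx(1.0)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentTable(6, 5, 5, 20)

    def test_matches_exact_enumeration_small_sweep(self):
        """Full agreement with the rational oracle for every table, N <= 12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        t = EnrichmentTable(k, n, K, N)
                        assert fisher_right_tail(t) == pytest.approx(
                            float(hypergeom_right_tail_exact(k, n, K, N)), rel=1e-9
                        )

    @given(
        st.integers(1, 25).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            ).flatmap(
                lambda t: st.tuples(
                    st.just(t[0]), st.just(t[1]), st.just(t[2]),
                    st.integers(max(0, t[1] + t[2] - t[0]), min(t[1], t[2])),
                )
            )
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_ease_never_below_fisher(self, nkk):
        N, K, n, k = nkk
        t = EnrichmentTable(k, n, K, N)
        assert ease_score(t) >= fisher_right_tail(t) - 1e-12


class TestOverlapCount:
    def test_distinct_features_count_fully(self):
        k, overlap, feats = overlap_count({"A", "B", "C"}, _match_map([("f1", "A"), ("f2", "B")]))
        assert k == 2 and overlap == {"A", "B"} and feats == {"f1", "f2"}

    def test_shared_feature_deflates_overlap(self):
        k, overlap, feats = overlap_count({"A", "B", "C"}, _match_map([("f1", "A"), ("f1", "B")]))
        assert k == 1 and overlap == {"A", "B"} and feats == {"f1"}

    def test_no_overlap(self):
        k, overlap, _ = overlap_count({"X"}, _match_map([("f1", "A")]))
        assert k == 0 and overlap == set()


@pytest.fixture(scope="module")
def context(default_fixture):
    model, L_ref, L_sig, _ = default_fixture
    index = TheoreticalIndex(model, build_derivative_table("positive"))
    return model, index, L_ref, L_sig


class TestPermutationNull:
    def test_pool_cardinality_one_permutation(self, context):
        model, index, L_ref, L_sig = context
        pool = build_null_pathway_pvalues(
            L_ref, 1, len(L_sig), model, index=index, rng=np.random.default_rng(5)
        )
        assert len(pool) == len(model.pathways)  # all 4 pathways are matchable

    def test_deterministic_under_seed(self, context):
        model, index, L_ref, L_sig = context
        pools = [
            build_null_pathway_pvalues(
                L_ref, 3, len(L_sig), model, index=index, rng=np.random.default_rng(9)
            )
            for _ in range(2)
        ]
        assert pools[0] == pools[1]

    def test_unmatchable_features_give_certain_pvalues(self, context):
        model, index, L_ref, L_sig = context
        # decoy-only table: no feature matches, k = 0 everywhere
        decoys = [i for i, f in enumerate(L_ref) if not index.lookup([f.mz], [f.feature_id], 10.0)]
        table = L_ref.subset(decoys[:30], role="reference")
        pool = build_null_pathway_pvalues(
            table, 2, 10, model, index=index, rng=np.random.default_rng(1)
        )
        assert all(p == pytest.approx(1.0) for p in pool)

    def test_pathway_universe_restricted_to_reference_coverage(self, context):
        """K comes from L_ref-matchable metabolites, never the full model."""
        model, index, L_ref, L_sig = context
        recs = index.lookup(L_sig.mz, L_sig.feature_ids, 10.0)
        matchable = frozenset(
            r.metabolite_id for r in index.lookup(L_ref.mz, L_ref.feature_ids, 10.0)
        )
        for r in enrich_pathways(model, MatchMap(recs), matchable):
            pw = model.pathway_by_id(r.pathway_id)
            assert r.table.K == len(pw.metabolite_ids & matchable)
            assert r.table.K <= len(pw.metabolite_ids)
            assert r.table.N_tot == len(matchable)


class TestAdjustedPvalue:
    def _null(self, seed=3, n=500):
        rng = np.random.default_rng(seed)
        return fit_pathway_null(rng.beta(2.0, 2.0, size=n))

    def test_certain_pvalue_stays_near_one(self):
        assert pathway_significance(1.0, self._null()) > 0.7

    def test_extreme_pvalue_beats_pool_resolution(self):
        null = self._null(n=500)
        assert pathway_significance(1e-12, null) < 1 / 500

    def test_monotone_in_ease_score(self):
        null = self._null()
        ps = [pathway_significance(x, null) for x in np.linspace(1e-6, 1.0, 40)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_empirical_fallback_ranks_pool(self):
        null = fit_pathway_null([0.2, 0.4, 0.6])  # too small -> fallback
        assert null.fallback
        assert pathway_significance(0.5, null) == pytest.approx(3 / 4)
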