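"""Overrepresentation machinery against independent oracles.

The hypergeometric tail is checked against exact rational enumeration; the
BH correction against a literal quadratic-time implementation of the
step-up definition; the pipeline against planted-term fixtures.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assocnet import (
    EnrichmentOptions,
    EnrichmentQuery,
    InvalidInputError,
    Term,
    TermCollection,
    benjamini_hochberg,
    group_terms,
    hypergeometric_tail,
    jaccard,
    min_achievable_pvalue,
    redundancy_filter,
    run_enrichment,
    signal,
    viable_term_size_range,
)
from assocnet.enrich import dotplot_table


def exact_tail(k: int, n: int, m: int, N: int) -> Fraction:
    """P(X >= k) by exact rational summation over the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(n, m) + 1):
        acc += Fraction(math.comb(m, j) * math.comb(N - m, n - j), total)
    return acc


def bh_reference(p: np.ndarray) -> np.ndarray:
    """Quadratic-time literal step-up: q_i = min over p_j >= p_i of p_j*T/rank_j."""
    T = len(p)
    ranks = np.array([(p <= pj).sum() for pj in p])
    candidates = p * T / ranks
    return np.array(
        [min(1.0, candidates[p >= pi].min()) for pi in p]
    )


class TestHypergeometricTail:
    @pytest.mark.parametrize(
        "k, n, m, N, expected",
        [
            (0, 5, 5, 20, 1.0),
            (5, 5, 5, 20, 1 / 15504),
            (1, 2, 1, 4, 0.5),
        ],
    )
    def test_worked_examples(self, k, n, m, N, expected):
        assert hypergeometric_tail(k, n, m, N) == pytest.approx(expected, rel=1e-12)

    def test_matches_rational_enumeration_on_moderate_sizes(self):
        for N in (8, 11):
            for n, m in itertools.product(range(N + 1), repeat=2):
                for k in range(min(n, m) + 1):
                    got = hypergeometric_tail(k, n, m, N)
                    assert got == pytest.approx(float(exact_tail(k, n, m, N)), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            hypergeometric_tail(6, 5, 5, 20)
        with pytest.raises(InvalidInputError):
            hypergeometric_tail(1, 5, 21, 20)


class TestMinAchievablePvalue:
    def test_single_gene_term_is_n_over_N(self):
        assert min_achievable_pvalue(1, 5, 50) == pytest.approx(0.1)

    def test_whole_background_term_is_one(self):
        assert min_achievable_pvalue(50, 5, 50) == pytest.approx(1.0)

    def test_large_term_closed_form(self):
        expected = math.comb(49, 5) / math.comb(50, 5)
        assert min_achievable_pvalue(49, 5, 50) == pytest.approx(expected, rel=1e-12)


class TestViableTermSizeRange:
    def test_worked_bound(self):
        m_lo, m_hi, _ = viable_term_size_range(5, 50, 0.05)
        assert (m_lo, m_hi) == (2, 28)

    def test_matches_size_scan_with_enumeration_oracle(self):
        N, n, alpha = 30, 6, 0.05
        viable = [
            m
            for m in range(1, N + 1)
            if exact_tail(min(m, n), n, m, N) <= Fraction(alpha).limit_denominator(10**6)
        ]
        m_lo, m_hi, _ = viable_term_size_range(n, N, alpha)
        assert m_lo == min(viable) and m_hi == max(viable)

    def test_alpha_near_one_excludes_almost_nothing(self):
        # only m = N stays excluded: a term covering the whole background has
        # best-case p exactly 1, above any alpha < 1
        sizes = {f"t{m}": m for m in range(1, 51)}
        m_lo, m_hi, excluded = viable_term_size_range(5, 50, 0.999999, sizes)
        assert (m_lo, m_hi) == (1, 49)
        assert excluded == ["t50"]

    def test_query_equal_background_nothing_viable(self):
        sizes = {"t": 10}
        m_lo, m_hi, excluded = viable_term_size_range(50, 50, 0.05, sizes)
        assert m_lo is None and m_hi is None
        assert excluded == ["t"]


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "pvalues, expected",
        [
            ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),
            ([0.2], [0.2]),
            ([0.3, 0.3, 0.3], [0.3, 0.3, 0.3]),
        ],
    )
    def test_worked_examples(self, pvalues, expected):
        assert benjamini_hochberg(pvalues) == pytest.approx(expected)

    def test_matches_quadratic_reference_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 120)))
            assert benjamini_hochberg(p) == pytest.approx(bh_reference(p), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_qvalues_dominate_pvalues_and_preserve_order(self, pvalues):
        p = np.array(pvalues)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(InvalidInputError):
            benjamini_hochberg([0.5, 1.5])


class TestSignal:
    def test_harmonic_mean_arithmetic(self):
        # a=4 corresponds to fdr=1e-2 giving b=2: (1+1)/(1/4+1/2) = 8/3
        assert signal(4.0, 1e-2) == pytest.approx(8 / 3)

    def test_equal_components_return_that_value(self):
        assert signal(3.0, 1e-3) == pytest.approx(3.0)

    def test_zero_fdr_weight_degenerates_to_ratio(self):
        assert signal(4.0, 0.5, w_fdr=0.0) == pytest.approx(4.0)

    def test_monotone_in_both_components(self):
        assert signal(4.0, 1e-3) > signal(2.0, 1e-3)
        assert signal(4.0, 1e-4) > signal(4.0, 1e-2)

    def test_no_evidence_gives_zero(self):
        assert signal(2.0, 1.0) == 0.0
        assert signal(0.0, 1e-3) == 0.0


class TestJaccardAndRedundancy:
    def test_jaccard_values(self):
        assert jaccard({"A"}, {"A"}) == 1.0
        assert jaccard({"A"}, {"B"}) == 0.0
        assert jaccard({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)
        with pytest.raises(InvalidInputError):
            jaccard(set(), {"A"})

    @staticmethod
    def _rows(members_list, pvalues):
        from assocnet.enrich import EnrichmentRow

        rows = []
        for i, (members, p) in enumerate(zip(members_list, pvalues)):
            term = Term(f"T{i}", "c", f"term {i}", frozenset(members))
            rows.append(
                EnrichmentRow(term, len(members), 1.0, len(members), p, p, 0.0, 1.0,
                              frozenset(members))
            )
        return rows

    def test_identical_sets_keep_only_lower_p(self):
        rows = self._rows([{"A", "B"}, {"A", "B"}], [0.01, 0.02])
        redundancy_filter(rows, 0.5)
        assert [r.kept for r in rows] == [True, False]

    def test_disjoint_sets_all_kept(self):
        rows = self._rows([{"A"}, {"B"}, {"C"}], [0.01, 0.02, 0.03])
        redundancy_filter(rows, 0.0)
        assert all(r.kept for r in rows)

    def test_comparison_only_against_kept_rows(self):
        # J(1,2)=0.6 > cutoff excludes 2; 3 is compared only against kept 1
        members = [
            {"a", "b", "c", "d", "e"},
            {"a", "b", "c", "d", "f", "g", "h"},  # J with 1 = 4/8? adjust below
            {"x", "y", "z", "e"},
        ]
        rows = self._rows(members, [0.01, 0.02, 0.03])
        j12 = jaccard(members[0], members[1])
        j13 = jaccard(members[0], members[2])
        j23 = jaccard(members[1], members[2])
        assert j12 > 0.4 and j13 <= 0.4 and j23 <= 0.4
        redundancy_filter(rows, 0.4)
        assert [r.kept for r in rows] == [True, False, True]

    def test_idempotent_on_its_own_kept_set(self):
        rng = np.random.default_rng(7)
        pool = [f"g{i}" for i in range(30)]
        members = [set(rng.choice(pool, size=rng.integers(2, 10), replace=False))
                   for _ in range(25)]
        rows = self._rows(members, list(rng.random(25)))
        redundancy_filter(rows, 0.3)
        kept = [r for r in rows if r.kept]
        again = redundancy_filter(list(kept), 0.3)
        assert all(r.kept for r in again)


class TestGroupTerms:
    @staticmethod
    def _rows(members_list, signals):
        from assocnet.enrich import EnrichmentRow

        rows = []
        for i, (members, s) in enumerate(zip(members_list, signals)):
            term = Term(f"T{i}", "c", f"term {i}", frozenset(members))
            rows.append(
                EnrichmentRow(term, len(members), 1.0, len(members), 0.01, 0.01,
                              0.0, s, frozenset(members))
            )
        return rows

    def test_all_disjoint_gives_singletons(self):
        rows = self._rows([{"a"}, {"b"}, {"c"}], [3.0, 2.0, 1.0])
        groups = group_terms(rows, 0.5)
        assert len(groups) == 3
        assert list(groups) == ["g1", "g2", "g3"]

    def test_identical_terms_merge(self):
        rows = self._rows([{"a", "b"}, {"a", "b"}], [1.0, 2.0])
        groups = group_terms(rows, 0.5)
        assert len(groups) == 1 and len(groups["g1"]) == 2
        # within-group order by signal descending
        assert [r.signal for r in groups["g1"]] == [2.0, 1.0]

    def test_linkage_trace_and_group_order_by_max_signal(self):
        members = [
            {"a", "b", "c", "d", "e"},
            {"a", "b", "c", "d", "f"},  # J(1,2) = 4/6
            {"x", "y", "z"},
        ]
        rows = self._rows(members, [1.0, 2.0, 5.0])
        groups = group_terms(rows, 0.5)
        assert len(groups) == 2
        # the singleton has the larger max signal, so it is g1
        assert [r.term.id for r in groups["g1"]] == ["T2"]
        assert {r.term.id for r in groups["g2"]} == {"T0", "T1"}

    def test_groups_meet_average_similarity_cutoff(self):
        rng = np.random.default_rng(11)
        pool = [f"g{i}" for i in range(25)]
        members = [set(rng.choice(pool, size=rng.integers(2, 8), replace=False))
                   for _ in range(20)]
        rows = self._rows(members, list(rng.random(20)))
        cutoff = 0.3
        for grp in group_terms(rows, cutoff).values():
            if len(grp) < 2:
                continue
            sims = [jaccard(a.members_effective, b.members_effective)
                    for a, b in itertools.combinations(grp, 2)]
            assert np.mean(sims) >= cutoff - 1e-12


class TestRunEnrichment:
    def test_planted_term_has_smallest_fdr(self):
        from assocnet import SynthConfig, synth_query_set, synth_term_collection

        universe = [f"G{i}" for i in range(60)]
        planted = set(universe[:15])
        coll, (pid,) = synth_term_collection(
            universe, {"planted process": planted}, SynthConfig(seed=5, n_noise_terms=80)
        )
        query = synth_query_set(coll, pid, 0.2, seed=5, universe=universe)
        rows = run_enrichment(query, coll, universe)
        bp = [r for r in rows if r.term.category == "GO Biological Process"]
        best = min(bp, key=lambda r: r.fdr)
        assert best.term.id == pid
        assert rows[0].term.id == pid  # also first by signal

    def test_query_equal_background_finds_nothing(self, small_collection):
        universe = small_collection.universe
        rows = run_enrichment(universe, small_collection, universe,
                              EnrichmentOptions(viability_filter=False))
        for row in rows:
            assert row.fdr == pytest.approx(1.0)
            assert row.ratio == pytest.approx(1.0)

    def test_empty_effective_query_warns_and_returns_empty(self, small_collection):
        with pytest.warns(UserWarning):
            rows = run_enrichment({"absent1", "absent2"}, small_collection)
        assert rows == []

    def test_viability_filter_never_hurts_the_tested_terms(self):
        # 1 real signal term among many single-gene noise terms
        rng = np.random.default_rng(3)
        universe = [f"G{i}" for i in range(100)]
        terms = [Term("SIG", "c", "signal", frozenset(universe[:10]))]
        terms += [
            Term(f"N{i}", "c", f"noise {i}", frozenset({universe[int(rng.integers(100))]}))
            for i in range(500)
        ]
        coll = TermCollection(terms)
        query = frozenset(universe[:8] + universe[90:92])
        filtered = run_enrichment(query, coll, universe, EnrichmentOptions())
        unfiltered = run_enrichment(query, coll, universe,
                                    EnrichmentOptions(viability_filter=False))
        f_by_id = {r.term.id: r for r in filtered}
        u_by_id = {r.term.id: r for r in unfiltered}
        assert "SIG" in f_by_id
        assert f_by_id["SIG"].fdr <= u_by_id["SIG"].fdr + 1e-15
        for tid, row in f_by_id.items():
            assert row.fdr <= u_by_id[tid].fdr + 1e-15

    def test_grouping_propagates_to_dotplot(self):
        universe = [f"G{i}" for i in range(40)]
        coll = TermCollection([
            Term("T1", "c", "one", frozenset(universe[:10])),
            Term("T2", "c", "two", frozenset(universe[:9])),
            Term("T3", "c", "three", frozenset(universe[20:30])),
        ])
        query = frozenset(universe[:10] + universe[20:25])
        rows = run_enrichment(query, coll, universe,
                              EnrichmentOptions(group_cutoff=0.5))
        records = dotplot_table(rows)
        assert [r.y_rank for r in records] == list(range(len(records)))
        groups = {}
        for r in records:
            groups.setdefault(r.group, []).append(r.term_id)
        assert sorted(len(v) for v in groups.values()) == [1, 2]

    def test_empty_rows_give_empty_dotplot(self):
        assert dotplot_table([]) == []
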