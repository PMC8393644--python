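"""Fisher over-representation, rank calibration, z-score and combined score."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar import (
    ContingencyTable,
    GeneSetLibrary,
    RankCalibration,
    adjust_bh,
    build_exchangeable_library,
    calibrate_ranks,
    combined_score,
    enrich,
    fisher_overrepresentation,
    simulate_null_query,
    z_score,
)
from famvar.enrich import EnrichmentError


def exact_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Independent oracle: exact integer summation of the hypergeometric tail."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / math.comb(N, n)


class TestContingencyTable:
    @pytest.mark.parametrize(
        "k, n, K, N",
        [(6, 5, 10, 20), (3, 5, 2, 20), (1, 25, 5, 20), (1, 5, 25, 20)],
    )
    def test_invalid_tables_rejected(self, k, n, K, N):
        with pytest.raises(EnrichmentError):
            ContingencyTable(k=k, n=n, K=K, N=N)


class TestFisher:
    def test_zero_overlap_has_p_one(self):
        assert fisher_overrepresentation(ContingencyTable(k=0, n=5, K=5, N=20)) == 1.0

    def test_degenerate_certain_overlap_has_p_one(self):
        assert fisher_overrepresentation(ContingencyTable(k=3, n=3, K=3, N=3)) == pytest.approx(1.0)

    def test_worked_example_matches_enumeration(self):
        # N=20, K=5, n=5, k=3: C(5,3)C(15,2)+C(5,4)C(15,1)+C(5,5) = 1126 over C(20,5)=15504
        p = fisher_overrepresentation(ContingencyTable(k=3, n=5, K=5, N=20))
        assert p == pytest.approx(1126 / 15504, rel=1e-14)
        assert p == pytest.approx(exact_upper_tail(3, 20, 5, 5), rel=1e-14)

    @settings(max_examples=150, derandomize=True)
    @given(data=st.data())
    def test_matches_exact_enumeration_on_random_tables(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        if K == 0 or n == 0:
            k = 0
        p = fisher_overrepresentation(ContingencyTable(k=k, n=n, K=K, N=N))
        assert p == pytest.approx(exact_upper_tail(k, N, K, n), rel=1e-12)

    def test_monotone_in_overlap(self):
        ps = [
            fisher_overrepresentation(ContingencyTable(k=k, n=10, K=15, N=100))
            for k in range(0, 11)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestCombinedScore:
    def test_p_one_or_z_zero_gives_zero(self):
        assert combined_score(1.0, 5.0) == 0.0
        assert combined_score(0.3, 0.0) == 0.0

    def test_closed_form(self):
        assert combined_score(math.exp(-4), 2.0) == pytest.approx(8.0)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(EnrichmentError):
            combined_score(p, 1.0)


class TestAdjustBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # step-up: min over j>=i of p_(j)*m/j, all equal to 0.04 here
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_one(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    @settings(max_examples=100, derandomize=True)
    @given(ps=st.lists(st.floats(1e-12, 1.0, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_at_most_one(self, ps):
        adj = adjust_bh(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)


def _disjoint_library(num_terms=10, term_size=8):
    genes = [f"G{i:04d}" for i in range(num_terms * term_size)]
    terms = {
        f"T{t:02d}": frozenset(genes[t * term_size : (t + 1) * term_size])
        for t in range(num_terms)
    }
    return GeneSetLibrary("disjoint", terms, background_size=len(genes))


class TestCalibration:
    def test_identical_seed_identical_calibration(self):
        lib = _disjoint_library()
        a = calibrate_ranks(lib, list_size=10, num_permutations=50, seed=9)
        b = calibrate_ranks(lib, list_size=10, num_permutations=50, seed=9)
        assert a == b

    def test_mean_of_mean_ranks_is_rank_conservation(self):
        # ranks of T terms always sum to T(T+1)/2, so the grand mean is exact
        lib = _disjoint_library(num_terms=12)
        cal = calibrate_ranks(lib, list_size=12, num_permutations=60, seed=3)
        grand = np.mean(list(cal.mean_rank.values()))
        assert grand == pytest.approx((12 + 1) / 2)

    def test_exchangeable_terms_share_the_expected_rank(self):
        # disjoint identically-sized terms are exchangeable: each mean rank
        # stays within 3 standard errors of (T+1)/2
        lib = _disjoint_library(num_terms=10, term_size=10)
        nperm = 400
        cal = calibrate_ranks(lib, list_size=20, num_permutations=nperm, seed=5)
        for term, mean in cal.mean_rank.items():
            se = cal.sd_rank[term] / math.sqrt(nperm)
            assert abs(mean - 5.5) < 3 * se + 0.3

    def test_sd_positive_for_every_term(self):
        lib = _disjoint_library()
        cal = calibrate_ranks(lib, list_size=10, num_permutations=50, seed=1)
        assert all(sd > 0 for sd in cal.sd_rank.values())

    def test_oversized_list_rejected(self):
        lib = _disjoint_library(num_terms=2, term_size=3)
        with pytest.raises(EnrichmentError):
            calibrate_ranks(lib, list_size=100, num_permutations=10, seed=0)


class TestZScore:
    def _cal(self):
        return RankCalibration(
            library_name="L", list_size=5, num_permutations=100, seed=0,
            mean_rank={"T": 4.0}, sd_rank={"T": 1.5},
        )

    def test_observed_at_mean_is_zero(self):
        assert z_score(4.0, self._cal(), "T") == 0.0

    def test_one_sd_better_than_expected_is_plus_one(self):
        assert z_score(4.0 - 1.5, self._cal(), "T") == pytest.approx(1.0)

    def test_unknown_term_is_error(self):
        with pytest.raises(EnrichmentError, match="NOPE"):
            z_score(1.0, self._cal(), "NOPE")


class TestEnrich:
    def test_query_equal_to_a_term_ranks_it_first(self):
        lib = _disjoint_library(num_terms=8, term_size=6)
        cal = calibrate_ranks(lib, list_size=6, num_permutations=100, seed=2)
        query = sorted(lib.terms["T03"])
        results = enrich(query, lib, cal, top_n=3)
        assert results[0].term == "T03"
        assert results[0].k == 6
        assert results[0].overlap_genes == tuple(query)

    def test_query_outside_every_term_scores_zero(self):
        lib = _disjoint_library(num_terms=4, term_size=4)
        cal = calibrate_ranks(lib, list_size=3, num_permutations=50, seed=2)
        results = enrich(["NOVEL1", "NOVEL2", "NOVEL3"], lib, cal, top_n=None)
        assert all(r.k == 0 and r.p_fisher == 1.0 and r.combined_score == 0.0 for r in results)

    def test_empty_query_is_error(self):
        lib = _disjoint_library()
        cal = calibrate_ranks(lib, list_size=4, num_permutations=10, seed=0)
        with pytest.raises(EnrichmentError, match="empty query"):
            enrich([], lib, cal)

    def test_combined_score_identity_holds_exactly(self):
        lib = _disjoint_library(num_terms=6, term_size=5)
        cal = calibrate_ranks(lib, list_size=8, num_permutations=80, seed=4)
        for r in enrich(sorted(lib.terms["T01"]) + ["XX1", "XX2", "XX3"], lib, cal, top_n=None):
            assert r.combined_score == pytest.approx(-math.log(r.p_fisher) * r.z, abs=1e-12)
            assert r.p_adjusted >= r.p_fisher - 1e-15


class TestNullQueries:
    def test_full_universe_query_is_the_universe(self):
        lib = _disjoint_library(num_terms=3, term_size=4)
        picks = simulate_null_query(lib, list_size=12, seed=0)
        assert sorted(picks) == sorted(lib.universe)

    def test_different_seeds_differ(self):
        lib = _disjoint_library(num_terms=5, term_size=10)
        assert simulate_null_query(lib, 10, seed=1) != simulate_null_query(lib, 10, seed=2)

    def test_exchangeable_library_terms_identically_sized(self):
        lib = build_exchangeable_library(num_terms=7, term_size=30, universe_size=200, seed=3)
        assert {len(g) for g in lib.terms.values()} == {30}
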