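"""Rank preferences, binomial and randomization nulls."""

import itertools

import numpy as np
import pandas as pd
import pytest

import codonaffinity as ca
from codonaffinity.genetic_code import Allocation
from codonaffinity.preferences import (
    RandomizationNull,
    binomial_preference_test,
    cognate_hit_summary,
    directionality_compare,
    first_choice_summary,
    randomization_null,
    rank_rows,
    rank_sum_score,
)


def mono_allocations(bases_by_aa):
    """One single-base allocation per amino acid."""
    return [
        Allocation(amino_acid=aa, position_scheme="anticodon2", family="..", bases=frozenset(b))
        for aa, b in bases_by_aa.items()
    ]


class TestRankRows:
    def test_tied_losers_average(self):
        m = pd.DataFrame([[0.9, 0.1, 0.1, 0.1]], index=["G"], columns=list("ACGU"))
        assert rank_rows(m).loc["G"].tolist() == [1.0, 3.0, 3.0, 3.0]

    def test_strictly_decreasing(self):
        m = pd.DataFrame([[4.0, 3.0, 2.0, 1.0]], index=["G"], columns=list("ACGU"))
        assert rank_rows(m).loc["G"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_rows_sum_to_ten(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((20, 4)), columns=list("ACGU"))
        assert (rank_rows(m).sum(axis=1) == 10.0).all()

    def test_missing_entries_listed(self):
        m = pd.DataFrame([[1.0, np.nan, 2.0, 3.0]], index=["G"], columns=list("ACGU"))
        with pytest.raises(ValueError, match="G/C"):
            rank_rows(m)


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,p,tail,expected",
        [
            (10, 20, 0.25, "upper", 0.0139),  # cognate-first enrichment
            (2, 23, 0.25, "lower", 0.0492),  # cognate-last depletion
            (19, 20, 0.75, "upper", 0.0243),  # best with >=1 cognate
        ],
    )
    def test_reported_tail_probabilities(self, k, n, p, tail, expected):
        assert binomial_preference_test(k, n, p, tail) == pytest.approx(expected, abs=5e-5)

    def test_k_zero_upper_is_one(self):
        assert binomial_preference_test(0, 15, 0.25, "upper") == 1.0

    def test_matches_enumeration_oracle(self):
        # brute force over all 4^n outcomes, success = one marked base
        n = 6
        for k in range(n + 1):
            count = sum(
                1
                for draw in itertools.product(range(4), repeat=n)
                if sum(x == 0 for x in draw) >= k
            )
            assert binomial_preference_test(k, n, 0.25, "upper") == pytest.approx(
                count / 4**n
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_preference_test(5, 3, 0.25)
        with pytest.raises(ValueError):
            binomial_preference_test(1, 3, 0.0)
        with pytest.raises(ValueError, match="tail"):
            binomial_preference_test(1, 3, 0.25, tail="middle")


class TestFirstChoice:
    def test_planted_cognates_all_first(self, planted_matrix, allocations):
        fc = first_choice_summary(planted_matrix, allocations)
        # planting puts one cognate middle base on top per amino acid; Ser's
        # second family carries the other cognate base, which is not on top
        assert fc["cognate_first"] == 22
        assert fc["n_allocations"] == 23

    def test_all_tied_no_strict_choice(self, allocations):
        m = pd.DataFrame(1.0, index=sorted({a.amino_acid for a in allocations}), columns=list("ACGU"))
        fc = first_choice_summary(m, allocations)
        assert fc["cognate_first"] == 0 and fc["cognate_last"] == 0

    def test_uniform_null_mean_quarter(self, allocations):
        # random matrices: each allocation's cognate tops its row w.p. 1/4
        rng = np.random.default_rng(42)
        aas = sorted({a.amino_acid for a in allocations})
        counts = []
        for _ in range(2000):
            m = pd.DataFrame(rng.random((len(aas), 4)), index=aas, columns=list("ACGU"))
            counts.append(first_choice_summary(m, allocations)["cognate_first"])
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 23 / 4) < 4 * se

    def test_cognate_hit_summary_planted(self, planted_matrix):
        hits = cognate_hit_summary(planted_matrix)
        assert hits["best_with_at_least_one"] == 20
        assert hits["best_with_none"] == 0


class TestRankSum:
    def test_bounds_twenty_amino_acids(self):
        bases = {aa: "U" for aa in "ACDEFGHIKLMNPQRSTVWY"}
        allocs = mono_allocations(bases)
        best = pd.DataFrame(
            [[1.0, 2.0, 3.0, 9.0]] * 20, index=list(bases), columns=list("ACGU")
        )
        worst = pd.DataFrame(
            [[9.0, 2.0, 3.0, 1.0]] * 20, index=list(bases), columns=list("ACGU")
        )
        assert rank_sum_score(rank_rows(best), allocs) == 20.0
        assert rank_sum_score(rank_rows(worst), allocs) == 80.0

    def test_minimum_with_hexacodonic_expansion(self, planted_matrix, allocations):
        # 23 allocations; every allocation of the planted matrix ranks its
        # cognate first except Ser's second family -> minimum possible is 23
        ranks = rank_rows(planted_matrix)
        score = rank_sum_score(ranks, allocations)
        assert score >= 23.0
        # 22 allocations rank 1; Ser's second cognate base contributes its rank
        top = planted_matrix.loc["S"].idxmax()
        other = next(iter(ca.cognate_bases("S", "anticodon2") - {top}))
        assert score == 22.0 + ranks.loc["S", other]


class TestRandomizationNull:
    def test_mean_is_two_point_five_per_allocation(self, allocations):
        null = randomization_null(allocations, n_randomizations=50_000, seed=1)
        se = null.sums.std() / np.sqrt(null.n_randomizations)
        assert abs(null.mean - 2.5 * 23) < 4 * se

    def test_bounds(self, allocations):
        null = randomization_null(allocations, n_randomizations=5_000, seed=2)
        assert null.sums.min() >= 23 and null.sums.max() <= 4 * 23

    def test_observed_minimum_beats_nearly_all(self, allocations):
        null = randomization_null(
            allocations, n_randomizations=20_000, seed=3, observed=23.0
        )
        # only the degenerate all-ranks-1 draw ties the minimum
        assert null.frac_stronger >= 1.0 - (0.25**23) * 20_000

    def test_seed_determinism(self, allocations):
        a = randomization_null(allocations, n_randomizations=1000, seed=4)
        b = randomization_null(allocations, n_randomizations=1000, seed=4)
        np.testing.assert_array_equal(a.sums, b.sums)

    def test_constraint_on_mononucleotides_warns_and_ignored(self, allocations):
        with pytest.warns(UserWarning, match="ignored"):
            null = randomization_null(
                allocations, n_randomizations=100, seed=5, dinucleotide_constraint=True
            )
        assert not null.dinucleotide_constraint

    def test_dinucleotide_constraint_forbids_identical_ranks(self):
        # one amino acid with two cognate dinucleotides: ranks drawn without
        # replacement, so the group's sum is never 2 (1+1) nor 8 (4+4)
        allocs = [
            Allocation("S", "codon12", "UC", frozenset(["UC"])),
            Allocation("S", "codon12", "AG", frozenset(["AG"])),
        ]
        constrained = randomization_null(
            allocs, n_columns=4, n_randomizations=5_000, seed=6, dinucleotide_constraint=True
        )
        assert constrained.sums.min() >= 3 and constrained.sums.max() <= 7
        free = randomization_null(allocs, n_columns=4, n_randomizations=5_000, seed=6)
        assert free.sums.min() == 2 and free.sums.max() == 8
        # both nulls share the same mean (2 * 2.5)
        assert abs(constrained.mean - 5.0) < 0.1


class TestDirectionality:
    @staticmethod
    def _series(occupancy, seed, n_runs=100):
        return ca.gen_distance_series(
            ca.TwoStateParams(occupancy=occupancy, n_runs=n_runs, n_frames=200, seed=seed)
        )

    def test_identical_series_difference_zero(self):
        s = self._series(0.3, seed=1, n_runs=10)
        res = directionality_compare(s, s.copy(), n_boot=500, seed=2)
        assert res["difference"] == 0.0
        assert res["ci95"][0] <= 0.0 <= res["ci95"][1]
        assert not res["excludes_zero"]

    def test_planted_difference_detected(self):
        xy = self._series(0.4, seed=3)
        yx = self._series(0.2, seed=4)
        res = directionality_compare(xy, yx, n_boot=2000, seed=5)
        assert res["difference"] > 0
        assert res["excludes_zero"]

    def test_antisymmetry(self):
        xy = self._series(0.35, seed=6, n_runs=10)
        yx = self._series(0.25, seed=7, n_runs=10)
        ab = directionality_compare(xy, yx, n_boot=500, seed=8)
        ba = directionality_compare(yx, xy, n_boot=500, seed=8)
        assert ab["difference"] == pytest.approx(-ba["difference"])

    def test_missing_orientation_rejected(self):
        s = self._series(0.3, seed=9, n_runs=5)
        with pytest.raises(ValueError, match="YX"):
            directionality_compare(s, pd.DataFrame())
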