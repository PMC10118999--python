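"""Penalty accounting, optimal exact tiling, greedy unit selection."""

from __future__ import annotations

import random
from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mosaictr.selection import (
    UNCOVERED,
    ExactDecomposition,
    UnitSet,
    best_exact_decomposition,
    greedy_select_units,
    penalty_of,
)
from mosaictr.strings import DnaString, enumerate_candidate_units

from conftest import random_dna
from oracles import brute_extended_penalty

S_RUN = DnaString("ACCGACCGACCG")
U_FULL = UnitSet.of("ACCG", "AC", "CG", "CGAC")


class TestPenalty:
    def test_unused_units_still_cost_their_length(self):
        d1 = ExactDecomposition.from_tiling(S_RUN, ["ACCG"] * 3)
        rep = penalty_of(d1, U_FULL)
        assert rep.penalty == 15  # (4+3)+(2+0)+(2+0)+(4+0)
        assert rep.extended_penalty == 15
        assert rep.coverage == 12

    def test_alternative_tilings(self):
        d2 = ExactDecomposition.from_tiling(S_RUN, ["AC", "CG"] * 3)
        d3 = ExactDecomposition.from_tiling(S_RUN, ["AC", "CGAC", "CGAC", "CG"])
        assert penalty_of(d2, U_FULL).penalty == 18
        assert penalty_of(d3, U_FULL).penalty == 16

    def test_pruned_unit_set(self):
        d1 = ExactDecomposition.from_tiling(S_RUN, ["ACCG"] * 3)
        assert penalty_of(d1, UnitSet.of("ACCG")).penalty == 7

    def test_uncovered_length_enters_extended_penalty_only(self):
        s = DnaString("ACCGTT")
        d = ExactDecomposition.from_tiling(s, ["AC", ("CGTT", UNCOVERED)])
        rep = penalty_of(d, UnitSet.of("AC"))
        assert (rep.penalty, rep.extended_penalty, rep.coverage) == (3, 7, 2)

    def test_label_outside_unit_set_rejected(self):
        d = ExactDecomposition.from_tiling(S_RUN, ["ACCG"] * 3)
        with pytest.raises(ValueError):
            penalty_of(d, UnitSet.of("AC"))


class TestFromTiling:
    def test_pieces_must_match_sequence(self):
        with pytest.raises(ValueError):
            ExactDecomposition.from_tiling(S_RUN, ["ACCG", "ACCG", "ACCC"])

    def test_pieces_must_tile_whole_sequence(self):
        with pytest.raises(ValueError):
            ExactDecomposition.from_tiling(S_RUN, ["ACCG", "ACCG"])


class TestBestExactDecomposition:
    @pytest.mark.parametrize(
        "unit, expected_ext",
        [("ACCG", 7), ("AC", 11), ("CG", 11), ("CGAC", 10)],
    )
    def test_first_round_scores_of_running_example(self, unit, expected_ext):
        u = UnitSet.of(unit)
        d = best_exact_decomposition(S_RUN, u)
        assert penalty_of(d, u).extended_penalty == expected_ext

    def test_empty_unit_set_leaves_all_uncovered(self):
        d = best_exact_decomposition(S_RUN, UnitSet(()))
        assert d.segments == ((0, 12, UNCOVERED),)
        assert penalty_of(d, UnitSet(())).extended_penalty == 12

    def test_adjacent_uncovered_merged(self):
        d = best_exact_decomposition(DnaString("ACGGGGAC"), UnitSet.of("AC"))
        assert d.segments == ((0, 2, "AC"), (2, 6, UNCOVERED), (6, 8, "AC"))

    def test_beats_hand_tilings(self):
        d = best_exact_decomposition(S_RUN, U_FULL)
        ext = penalty_of(d, U_FULL).extended_penalty
        for pieces in (["ACCG"] * 3, ["AC", "CG"] * 3, ["AC", "CGAC", "CGAC", "CG"]):
            hand = ExactDecomposition.from_tiling(S_RUN, pieces)
            assert ext <= penalty_of(hand, U_FULL).extended_penalty

    def test_matches_exhaustive_tiling_search(self):
        rnd = random.Random(7)
        unit_pool = ["A", "C", "AC", "CA", "ACG", "CGA", "AAC", "G"]
        for _ in range(120):
            seq = random_dna(rnd, rnd.randint(1, 15), "ACG")
            units = tuple(rnd.sample(unit_pool, rnd.randint(0, 3)))
            u = UnitSet(units)
            d = best_exact_decomposition(DnaString(seq), u)
            assert (
                penalty_of(d, u).extended_penalty
                == brute_extended_penalty(seq, units)
            )


def _greedy_ext(seq: str) -> int:
    s = DnaString(seq)
    cands = enumerate_candidate_units(s, 100)
    _, _, rep = greedy_select_units(s, cands)
    return rep.extended_penalty


class TestGreedySelection:
    def test_running_example_selects_single_unit(self):
        s = S_RUN
        units, d, rep = greedy_select_units(s, enumerate_candidate_units(s))
        assert units.units == ("ACCG",)
        assert rep.extended_penalty == 7
        assert d.segments == ((0, 4, "ACCG"), (4, 8, "ACCG"), (8, 12, "ACCG"))

    def test_empty_candidates_returns_uncovered_string(self):
        s = DnaString("ACGT")
        units, d, rep = greedy_select_units(s, [])
        assert len(units) == 0
        assert rep.extended_penalty == 4

    def test_homopolymer_not_worth_a_unit(self):
        # unit "A" would cost 1 + 8 = 9 > 8 uncovered bases: greedy declines
        s = DnaString("AAAAAAAA")
        units, _, rep = greedy_select_units(s, enumerate_candidate_units(s))
        assert units.units == ()
        assert rep.extended_penalty == 8

    def test_zero_occurrence_units_eliminated(self):
        s = S_RUN
        units, d, _ = greedy_select_units(s, enumerate_candidate_units(s))
        occ = d.occurrences()
        assert all(occ[u] > 0 for u in units)

    @given(
        st.sampled_from(["AC", "AG", "ACG", "AAG", "AAAG", "ACCGT", "AACGGT"]),
        st.integers(3, 12),
    )
    def test_perfect_repeat_recovers_its_unit(self, unit, k):
        s = DnaString(unit * k)
        units, _, rep = greedy_select_units(s, enumerate_candidate_units(s))
        assert units.units == (unit,)
        assert rep.extended_penalty == len(unit) + k

    def test_greedy_bounded_below_by_exhaustive_minimum(self):
        rnd = random.Random(11)
        for _ in range(30):
            seq = random_dna(rnd, rnd.randint(4, 12), "ACG")
            s = DnaString(seq)
            cands = [c.text for c in enumerate_candidate_units(s)]
            best = len(seq)  # empty unit set
            for r in range(1, min(len(cands), 3) + 1):
                for subset in combinations(cands, r):
                    best = min(best, brute_extended_penalty(seq, subset))
            assert _greedy_ext(seq) >= best

    def test_mosaic_two_unit_string_selects_both_units(self):
        s = DnaString("AC" * 20 + "AG" * 30)
        units, _, rep = greedy_select_units(s, enumerate_candidate_units(s))
        assert set(units.units) == {"AC", "AG"}
        assert rep.extended_penalty == 2 + 20 + 2 + 30
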