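"""Local alignment, matrix routing and E-value statistics.

The independent oracle scores local alignments by exhaustive substring
decomposition: for every pair of substrings, the best *global* affine-gap
alignment is computed by plain memoized recursion over edit states, and the
local score is the maximum over all substring pairs (floored at zero).
"""
from __future__ import annotations

import math
from functools import lru_cache

import pytest
from hypothesis import given, settings, strategies as st

from lsgscan import ProteinRecord, evalue, has_hit, scoring_scheme, select_matrix, smith_waterman
from lsgscan.homology import local_score

BL62 = scoring_scheme("BLOSUM62")
ORACLE_ALPHABET = "ACDE"


def oracle_global_affine(a: str, b: str, scheme) -> float:
    """Best global affine alignment score of a vs b (recursive, memoized)."""
    go, ge = -scheme.gap_open, -scheme.gap_extend  # positive costs
    sub = scheme.matrix

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        opts = []
        if i < len(a) and j < len(b):
            opts.append(sub[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = ge if state == "D" else go + ge
            opts.append(-cost + rec(i + 1, j, "D"))
        if j < len(b):
            cost = ge if state == "I" else go + ge
            opts.append(-cost + rec(i, j + 1, "I"))
        return max(opts)

    return rec(0, 0, "S")


def oracle_local_score(a: str, b: str, scheme) -> float:
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(
                        best, oracle_global_affine(a[i0:i1], b[j0:j1], scheme)
                    )
    return best


class TestMatrixSelection:
    @pytest.mark.parametrize(
        "length,expected",
        [(25, "PAM30"), (29, "PAM30"), (30, "PAM70"), (50, "PAM70"),
         (70, "PAM70"), (71, "BLOSUM62"), (100, "BLOSUM62")],
    )
    def test_length_classes(self, length, expected):
        assert select_matrix(length) == expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            select_matrix(0)

    def test_bounds_configurable(self):
        assert select_matrix(40, bounds=(50, 90)) == "PAM30"


class TestSmithWaterman:
    def test_identity_alignment_sums_diagonal(self):
        # M/K/V diagonal entries of the published BLOSUM62 table: 5 + 5 + 4
        q = ProteinRecord("q", "MKV")
        hit = smith_waterman(q, ProteinRecord("t", "MKV"), BL62)
        assert hit is not None
        assert hit.raw_score == 14
        assert hit.identity_frac == 1.0
        assert hit.query_range == (0, 3)

    def test_all_negative_pairs_give_none(self):
        # A vs C scores 0 under BLOSUM62? no: s(A,C) = 0 -> pick a truly
        # negative pair: A vs D is -2, so AAAA vs DDDD has no positive local
        q = ProteinRecord("q", "AAAA")
        assert smith_waterman(q, ProteinRecord("t", "DDDD"), BL62) is None

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman(ProteinRecord("q", "MKB"), ProteinRecord("t", "MKV"), BL62)

    def test_x_scores_zero_everywhere(self):
        assert BL62.matrix["X", "W"] == 0.0
        assert BL62.matrix["X", "X"] == 0.0

    def test_mismatch_and_gap_pair_matches_enumeration(self):
        # 10 aa vs 12 aa with a mismatch and an indel
        a, b = "ACDEACDEAC", "ACDEEACDDEAC"
        assert local_score(a, b, BL62) == oracle_local_score(a, b, BL62)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.text(ORACLE_ALPHABET, min_size=1, max_size=8),
        st.text(ORACLE_ALPHABET, min_size=1, max_size=8),
    )
    def test_dp_equals_bruteforce_enumeration(self, a, b):
        assert local_score(a, b, BL62) == pytest.approx(oracle_local_score(a, b, BL62))

    def test_dp_equals_bruteforce_exhaustive_short(self):
        seqs = [x + y for x in ORACLE_ALPHABET for y in ORACLE_ALPHABET]
        for a in seqs:
            for b in seqs:
                assert local_score(a, b, BL62) == oracle_local_score(a, b, BL62)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.text(ORACLE_ALPHABET, min_size=1, max_size=8),
        st.text(ORACLE_ALPHABET, min_size=1, max_size=8),
        st.text(ORACLE_ALPHABET, min_size=0, max_size=4),
    )
    def test_symmetry_and_extension_monotonicity(self, a, b, extra):
        assert local_score(a, b, BL62) == local_score(b, a, BL62)
        assert local_score(a, b + extra, BL62) >= local_score(a, b, BL62)


class TestEvalue:
    def test_closed_form(self):
        # E = 0.041 * 100 * 10000 * exp(-0.267*50), evaluated independently
        scheme = scoring_scheme("BLOSUM62")
        expected = 0.041 * 1e6 * math.exp(-13.35)
        assert evalue(50, 100, 10_000, scheme) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.06533, rel=1e-3)

    def test_large_score_limit(self):
        assert evalue(10_000, 100, 10_000, BL62) == pytest.approx(0.0, abs=1e-300)

    def test_linear_in_database_size(self):
        e1 = evalue(50, 100, 10_000, BL62)
        assert evalue(50, 100, 20_000, BL62) == pytest.approx(2 * e1)
        assert evalue(50, 200, 10_000, BL62) == pytest.approx(2 * e1)

    def test_strictly_decreasing_in_score(self):
        assert evalue(51, 100, 10_000, BL62) < evalue(50, 100, 10_000, BL62)

    def test_bad_lengths_rejected(self):
        with pytest.raises(ValueError):
            evalue(50, 0, 10_000, BL62)


class TestHasHit:
    QUERY = ProteinRecord("q", "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQT")

    def test_empty_panel_false(self):
        assert has_hit(self.QUERY, []) is False

    def test_self_match_true(self):
        assert has_hit(self.QUERY, [ProteinRecord("t", self.QUERY.sequence)]) is True

    def test_unrelated_false(self):
        junk = ProteinRecord("t", "GGGGGGGGGGPPPPPPPPPPGGGGGGGGGG")
        assert has_hit(self.QUERY, [junk]) is False

    def test_monotone_in_cutoff(self):
        panel = [ProteinRecord("t", self.QUERY.sequence)]
        assert has_hit(self.QUERY, panel, cutoff=1e-6)
        assert has_hit(self.QUERY, panel, cutoff=1e-5)
        # a hit at the stricter cutoff implies a hit at the looser one
        for cutoff in (1e-30, 1e-10, 1e-5, 1e-3):
            if has_hit(self.QUERY, panel, cutoff=cutoff):
                assert has_hit(self.QUERY, panel, cutoff=cutoff * 10)
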