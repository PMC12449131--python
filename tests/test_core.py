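"""Serial kernel: substitution scores, matrix fill, maximum, traceback."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actalign.core import (
    AlignmentResult,
    BacktrackPolicy,
    ConfigurationError,
    InvalidResidueError,
    ScoringScheme,
    Sequence,
    align_serial,
    backtrack,
    cigar_string,
    fill_matrices,
    find_max,
    rescore_alignment,
    substitution_score,
)
from conftest import WORKED_P, WORKED_Q, random_pair
from oracle import oracle_best, oracle_matrices

DNA = st.text(alphabet="ACGT", min_size=0, max_size=25)


class TestTypes:
    def test_sequence_validates_alphabet_and_id(self):
        s = Sequence("s1", "acgtn")
        assert s.residues == "ACGTN" and s.length == 5
        with pytest.raises(InvalidResidueError):
            Sequence("s2", "ACGX")
        with pytest.raises(ValueError):
            Sequence("", "ACGT")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(match_score=1, mismatch_score=1, gap_open_extend=2, gap_extend=2),
            dict(match_score=2, mismatch_score=-1, gap_open_extend=1, gap_extend=2),
            dict(match_score=2, mismatch_score=-1, gap_open_extend=2, gap_extend=-1),
            dict(match_score=2, mismatch_score=-1, gap_open_extend=3, gap_extend=2,
                 gap_mode="linear"),
        ],
    )
    def test_scheme_invariants(self, kwargs):
        with pytest.raises(ConfigurationError):
            ScoringScheme(**{"gap_mode": "affine", **kwargs})
        # the linear-mode Goe==Ge violation is checked via its own kwargs

    def test_signed_gap_stored_as_magnitude(self):
        s = ScoringScheme.linear(2, -1, -2)
        assert s.gap_open_extend == s.gap_extend == 2

    def test_policy_validation(self):
        with pytest.raises(ConfigurationError):
            BacktrackPolicy(threshold=-1)
        with pytest.raises(ConfigurationError):
            BacktrackPolicy(tie_order=("diagonal", "diagonal", "up"))


class TestSubstitutionScore:
    @pytest.mark.parametrize(
        "a,b,match,mismatch,expected",
        [
            ("A", "A", 3, 1, 3),
            ("A", "A", 2, -1, 2),
            ("A", "T", 2, -1, -1),
            ("N", "N", 2, -1, -1),  # ambiguity never matches, even itself
            ("a", "A", 2, -1, 2),  # case folding
        ],
    )
    def test_examples(self, a, b, match, mismatch, expected):
        sch = ScoringScheme.linear(match, mismatch, -2)
        assert substitution_score(a, b, sch) == expected

    def test_rejects_residue_outside_alphabet(self, scheme):
        with pytest.raises(InvalidResidueError):
            substitution_score("A", "X", scheme)


class TestFillMatrices:
    def test_empty_query_gives_zero_row(self, scheme):
        mats = fill_matrices(Sequence("p", ""), Sequence("q", "ACGT"), scheme)
        assert mats.H.shape == (1, 5)
        assert np.all(mats.H == 0)

    def test_single_match(self, scheme):
        mats = fill_matrices(Sequence("p", "A"), Sequence("q", "A"), scheme)
        assert mats.H[1][1] == 2
        assert find_max(mats) == (2, 1, 1)

    def test_worked_example_max_is_six(self, worked_pair, scheme):
        p, q = worked_pair
        mats = fill_matrices(p, q, scheme)
        assert int(mats.H.max()) == 6

    def test_worked_example_matches_oracle_entrywise(self, worked_pair, scheme):
        p, q = worked_pair
        mats = fill_matrices(p, q, scheme)
        Ht, Et, Ft = oracle_matrices(p.residues, q.residues, 2, -1, 2, 2)
        assert mats.H.tolist() == Ht
        assert mats.E[1:, 1:].tolist() == [row[1:] for row in Et[1:]]
        assert mats.F[1:, 1:].tolist() == [row[1:] for row in Ft[1:]]

    @pytest.mark.parametrize("goe,ge,mode", [(2, 2, "linear"), (4, 1, "affine")])
    def test_random_pairs_match_oracle(self, goe, ge, mode):
        rng = np.random.default_rng(42)
        sch = ScoringScheme(2, -1, goe, ge, mode)
        for _ in range(25):
            p, q = random_pair(rng, 30)
            mats = fill_matrices(p, q, sch)
            Ht, Et, Ft = oracle_matrices(p.residues, q.residues, 2, -1, goe, ge)
            assert mats.H.tolist() == Ht
            assert mats.E[1:, 1:].tolist() == [row[1:] for row in Et[1:]]
            assert mats.F[1:, 1:].tolist() == [row[1:] for row in Ft[1:]]


class TestFindMax:
    def test_all_zero_matrix_reports_no_alignment(self, scheme):
        mats = fill_matrices(Sequence("p", "AAAA"), Sequence("q", "TTTT"), scheme)
        assert find_max(mats) == (0, None, None)

    def test_perfect_match_diagonal(self, scheme):
        mats = fill_matrices(Sequence("p", "ACG"), Sequence("q", "ACG"), scheme)
        assert find_max(mats) == (6, 3, 3)

    def test_worked_example_tie_broken_to_smallest_ij(self, worked_pair, scheme):
        p, q = worked_pair
        mats = fill_matrices(p, q, scheme)
        assert find_max(mats) == (6, 3, 6)
        assert mats.H[4][8] == 6  # the co-maximum the tie rule must skip


class TestBacktrack:
    def test_single_match(self, scheme):
        p, q = Sequence("p", "A"), Sequence("q", "A")
        mats = fill_matrices(p, q, scheme)
        r = backtrack(mats, p, q, scheme, (1, 1))
        assert (r.aligned_query, r.aligned_target) == ("A", "A")
        assert r.cigar == "1M"
        assert (r.query_start, r.query_end, r.target_start, r.target_end) == (1, 1, 1, 1)

    def test_perfect_triplet(self, scheme):
        p = q = Sequence("p", "ACG")
        r = align_serial(p, q, scheme)
        assert (r.aligned_query, r.aligned_target, r.cigar, r.score) == ("ACG", "ACG", "3M", 6)

    def test_worked_example_traceback(self, worked_pair, scheme):
        p, q = worked_pair
        mats = fill_matrices(p, q, scheme)
        r = backtrack(mats, p, q, scheme, (3, 6))
        assert (r.aligned_query, r.aligned_target) == ("ATC", "ATC")
        assert (r.query_start, r.query_end) == (1, 3)
        assert (r.target_start, r.target_end) == (4, 6)
        assert r.score == 6

    def test_out_of_bounds_start(self, worked_pair, scheme):
        p, q = worked_pair
        mats = fill_matrices(p, q, scheme)
        with pytest.raises(IndexError):
            backtrack(mats, p, q, scheme, (99, 1))

    def test_rescoring_consistency_random(self, affine_scheme):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p, q = random_pair(rng, 40)
            r = align_serial(p, q, affine_scheme)
            if not r.is_empty:
                assert rescore_alignment(r.aligned_query, r.aligned_target, affine_scheme) == r.score

    def test_coordinates_recover_residue_ranges(self, scheme):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p, q = random_pair(rng, 40)
            r = align_serial(p, q, scheme)
            if r.is_empty:
                continue
            assert r.aligned_query.replace("-", "") == p.residues[r.query_start - 1 : r.query_end]
            assert r.aligned_target.replace("-", "") == q.residues[r.target_start - 1 : r.target_end]


class TestAlignSerial:
    def test_self_alignment_scores_twice_length(self, scheme):
        rng = np.random.default_rng(3)
        p, _ = random_pair(rng, 60, min_len=10)
        r = align_serial(p, p, scheme)
        assert r.score == 2 * len(p)
        assert r.cigar == f"{len(p)}M"

    def test_all_mismatch_pair_is_empty(self, scheme):
        r = align_serial(Sequence("p", "AAAA"), Sequence("q", "TTTT"), scheme)
        assert r.is_empty and r.score == 0
        assert r.aligned_query == "" and r.cigar == ""

    def test_worked_example_score(self, worked_pair, scheme):
        assert align_serial(*worked_pair, scheme).score == 6

    def test_score_only_matches_full_mode_ends(self, scheme):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p, q = random_pair(rng, 60)
            full = align_serial(p, q, scheme)
            so = align_serial(p, q, scheme, score_only=True)
            assert so.score == full.score
            if not full.is_empty:
                assert (so.query_end, so.target_end) == (full.query_end, full.target_end)
                assert so.aligned_query == "" and so.is_score_only


class TestKernelProperties:
    @settings(max_examples=60, deadline=None)
    @given(DNA, DNA)
    def test_nonnegativity_and_zero_boundary(self, ps, qs):
        sch = ScoringScheme.linear(2, -1, -2)
        mats = fill_matrices(Sequence("p", ps or "A"), Sequence("q", qs or "A"), sch)
        assert np.all(mats.H >= 0)
        assert np.all(mats.H[0, :] == 0) and np.all(mats.H[:, 0] == 0)

    @settings(max_examples=60, deadline=None)
    @given(DNA.filter(bool), DNA.filter(bool))
    def test_score_symmetry(self, ps, qs):
        sch = ScoringScheme.linear(2, -1, -2)
        p, q = Sequence("p", ps), Sequence("q", qs)
        rf = align_serial(p, q, sch)
        rb = align_serial(q, p, sch)
        assert rf.score == rb.score

    @settings(max_examples=40, deadline=None)
    @given(DNA.filter(bool), DNA.filter(bool), DNA, DNA)
    def test_extension_monotonicity(self, ps, qs, xs, ys):
        sch = ScoringScheme.linear(2, -1, -2)
        base = align_serial(Sequence("p", ps), Sequence("q", qs), sch).score
        assert align_serial(Sequence("p", ps + xs), Sequence("q", qs), sch).score >= base
        assert align_serial(Sequence("p", ps), Sequence("q", qs + ys), sch).score >= base


def test_cigar_string_runs():
    assert cigar_string("ACG", "ACG") == "3M"
    assert cigar_string("AC-GT", "ACCGT") == "2M1D2M"
    assert cigar_string("ACGT", "AC-T") == "2M1I1M"
    assert cigar_string("A--T", "AGCT") == "1M2D1M"
    with pytest.raises(ValueError):
        cigar_string("A-", "A")
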