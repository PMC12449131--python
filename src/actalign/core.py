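"""Serial Smith-Waterman local alignment kernel with Gotoh gap states.

This is the ground-truth kernel: every parallel execution path in the
package (blockwise wavefront, actor topology) must reproduce its output
bit-for-bit.  The recursions over the three dynamic-programming matrices
are, for sequences ``p`` (length ``m``) and ``q`` (length ``n``)::

    H[i][0] = H[0][j] = 0
    H[i][j] = max(0, H[i-1][j-1] + s(p_i, q_j), E[i][j], F[i][j])
    E[i][j] = max(H[i][j-1] - Goe, E[i][j-1] - Ge)     # gap in query
    F[i][j] = max(H[i-1][j] - Goe, F[i-1][j] - Ge)     # gap in target

where ``s`` is the match/mismatch substitution score, ``Goe`` the combined
gap open+extend penalty and ``Ge`` the gap extension penalty.  The linear
gap model is the special case ``Goe == Ge``.  All scoring is integer; the
kernel never touches floating point, so results are exactly reproducible
across block sizes and schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

import numpy as np
from numba import njit

DNA_ALPHABET = "ACGTN"

#: Sentinel for gap states that do not exist yet (e.g. E in column 0).
#: Far below any reachable score, but safe against int64 underflow.
NEG_SENTINEL = -(1 << 40)


class InvalidResidueError(ValueError):
    """A residue falls outside the declared alphabet."""


class ConfigurationError(ValueError):
    """A scoring scheme or job parameter violates its invariants."""


@dataclass(frozen=True)
class Sequence:
    """An identified residue string over a declared alphabet.

    Residues are case-folded to upper case on construction.  The default
    alphabet is DNA with ``N`` as the ambiguity code; ``N`` scores as a
    mismatch against every residue, including another ``N``.
    """

    id: str
    residues: str
    alphabet: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        object.__setattr__(self, "alphabet", self.alphabet.upper())
        allowed = set(self.alphabet)
        bad = set(self.residues) - allowed
        if bad:
            raise InvalidResidueError(
                f"sequence {self.id!r}: residues {sorted(bad)} outside "
                f"alphabet {self.alphabet!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @cached_property
    def codes(self) -> np.ndarray:
        """Residues encoded as uint8 indices into the alphabet."""
        table = {c: k for k, c in enumerate(self.alphabet)}
        return np.frombuffer(
            bytes(table[c] for c in self.residues), dtype=np.uint8
        ).copy()

    @property
    def ambiguity_code(self) -> int:
        """Code of the always-mismatch residue ('N'), or 255 if absent."""
        k = self.alphabet.find("N")
        return k if k >= 0 else 255


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and gap penalties.

    ``gap_open_extend`` (Goe) is the combined cost of opening a gap (it
    already includes the first extension); ``gap_extend`` (Ge) is the cost
    of each further gapped position.  Both are stored as non-negative
    magnitudes and subtracted in the recursion.  ``gap_mode`` is ``linear``
    (Goe == Ge, a constant per-symbol gap cost) or ``affine``.
    """

    match_score: int
    mismatch_score: int
    gap_open_extend: int
    gap_extend: int
    gap_mode: str = "linear"

    def __post_init__(self) -> None:
        if self.gap_mode not in ("linear", "affine"):
            raise ConfigurationError(f"unknown gap_mode {self.gap_mode!r}")
        if self.match_score <= self.mismatch_score:
            raise ConfigurationError("match_score must exceed mismatch_score")
        if not (self.gap_open_extend >= self.gap_extend >= 0):
            raise ConfigurationError(
                "need gap_open_extend >= gap_extend >= 0, got "
                f"Goe={self.gap_open_extend}, Ge={self.gap_extend}"
            )
        if self.gap_mode == "linear" and self.gap_open_extend != self.gap_extend:
            raise ConfigurationError("linear mode requires Goe == Ge")

    @classmethod
    def linear(cls, match: int, mismatch: int, gap: int) -> "ScoringScheme":
        """Linear-gap scheme; ``gap`` may be given signed (as printed by
        most tools, e.g. ``gap=-2``) and is stored as a magnitude."""
        return cls(match, mismatch, abs(gap), abs(gap), "linear")

    @classmethod
    def affine(
        cls, match: int, mismatch: int, gap_open_extend: int, gap_extend: int
    ) -> "ScoringScheme":
        return cls(match, mismatch, abs(gap_open_extend), abs(gap_extend), "affine")


@dataclass
class DPMatrices:
    """The H, E, F score matrices for one pair, shape (m+1, n+1)."""

    H: np.ndarray
    E: np.ndarray
    F: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.H.shape


@dataclass(frozen=True)
class BacktrackPolicy:
    """Where traceback stops and how move ties are broken.

    Traceback walks predecessor cells from the maximum until it reaches a
    cell whose H value is at or below ``threshold`` (conventionally 0).
    ``tie_order`` fixes the preference among equally-scoring provenance
    moves so that every execution path reconstructs the same alignment.
    """

    threshold: int = 0
    tie_order: tuple = ("diagonal", "up", "left")

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if sorted(self.tie_order) != ["diagonal", "left", "up"]:
            raise ConfigurationError(
                "tie_order must be a permutation of (diagonal, up, left)"
            )


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment: score, 1-based inclusive coordinates, gapped
    strings and a CIGAR over {M, I, D} (I = gap in target, D = gap in
    query).  A score-0 / no-alignment result carries zero coordinates and
    empty strings; score-only results carry end coordinates, zero start
    coordinates and a ``*`` CIGAR."""

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_query: str
    aligned_target: str
    cigar: str

    @property
    def is_empty(self) -> bool:
        return self.score == 0 and self.query_end == 0

    @property
    def is_score_only(self) -> bool:
        return self.cigar == "*"


# ---------------------------------------------------------------------------
# numba kernels (integer-only, GIL-free so actor worker threads can overlap)
# ---------------------------------------------------------------------------


@njit(nogil=True, cache=True)
def _fill_from_halo(
    pc, qc, top_h, top_f, left_h, left_e, corner_h, match, mismatch, goe, ge, ncode
):  # pragma: no cover - exercised via wrappers
    bm = pc.shape[0]
    bn = qc.shape[0]
    H = np.empty((bm + 1, bn + 1), np.int64)
    E = np.empty((bm + 1, bn + 1), np.int64)
    F = np.empty((bm + 1, bn + 1), np.int64)
    H[0, 0] = corner_h
    for j in range(bn):
        H[0, j + 1] = top_h[j]
        F[0, j + 1] = top_f[j]
    F[0, 0] = NEG_SENTINEL
    for i in range(bm):
        H[i + 1, 0] = left_h[i]
        E[i + 1, 0] = left_e[i]
    E[0, :] = NEG_SENTINEL
    F[1:, 0] = NEG_SENTINEL
    for i in range(1, bm + 1):
        a = pc[i - 1]
        for j in range(1, bn + 1):
            e = H[i, j - 1] - goe
            t = E[i, j - 1] - ge
            if t > e:
                e = t
            f = H[i - 1, j] - goe
            t = F[i - 1, j] - ge
            if t > f:
                f = t
            if a == qc[j - 1] and a != ncode:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] + mismatch
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(nogil=True, cache=True)
def _score_only_rolling(
    pc, qc, match, mismatch, goe, ge, ncode
):  # pragma: no cover - exercised via wrappers
    """Best score and end cell with O(n) memory (two rolling rows)."""
    m = pc.shape[0]
    n = qc.shape[0]
    h_prev = np.zeros(n + 1, np.int64)
    h_cur = np.zeros(n + 1, np.int64)
    f_row = np.full(n + 1, NEG_SENTINEL, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        a = pc[i - 1]
        e = NEG_SENTINEL
        h_cur[0] = 0
        for j in range(1, n + 1):
            t = h_cur[j - 1] - goe
            e = e - ge
            if t > e:
                e = t
            f = h_prev[j] - goe
            t = f_row[j] - ge
            if t > f:
                f = t
            f_row[j] = f
            if a == qc[j - 1] and a != ncode:
                h = h_prev[j - 1] + match
            else:
                h = h_prev[j - 1] + mismatch
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        h_prev, h_cur = h_cur, h_prev
    return best, bi, bj


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def substitution_score(a: str, b: str, scheme: ScoringScheme, alphabet: str = DNA_ALPHABET) -> int:
    """Score for pairing residues ``a`` and ``b``: match_score on identity,
    mismatch_score otherwise.  The ambiguity residue 'N' never matches."""
    a, b = a.upper(), b.upper()
    for r in (a, b):
        if r not in alphabet:
            raise InvalidResidueError(f"residue {r!r} outside alphabet {alphabet!r}")
    if a == b and a != "N":
        return scheme.match_score
    return scheme.mismatch_score


def _check_pair_alphabet(p: Sequence, q: Sequence) -> None:
    if p.alphabet != q.alphabet:
        raise ConfigurationError(
            f"sequences {p.id!r} and {q.id!r} declare different alphabets"
        )


def fill_matrices(p: Sequence, q: Sequence, scheme: ScoringScheme) -> DPMatrices:
    """Compute the full H, E, F matrices for one pair.

    Empty sequences are legal and yield an all-zero H.  Shapes are
    (m+1, n+1) with the zero boundary in row 0 and column 0.
    """
    _check_pair_alphabet(p, q)
    m, n = len(p), len(q)
    H, E, F = _fill_from_halo(
        p.codes,
        q.codes,
        np.zeros(n, np.int64),
        np.full(n, NEG_SENTINEL, np.int64),
        np.zeros(m, np.int64),
        np.full(m, NEG_SENTINEL, np.int64),
        0,
        scheme.match_score,
        scheme.mismatch_score,
        scheme.gap_open_extend,
        scheme.gap_extend,
        p.ambiguity_code,
    )
    return DPMatrices(H, E, F)


def find_max(mats: DPMatrices):
    """Locate the optimal local alignment score S in H.

    Returns ``(score, i, j)`` with ties broken by smallest ``i`` then
    smallest ``j``; an all-zero H (no positive-scoring cell) returns
    ``(0, None, None)``.
    """
    H = mats.H
    flat = int(np.argmax(H))  # C-order argmax = first occurrence = smallest (i, j)
    score = int(H.flat[flat])
    if score == 0:
        return 0, None, None
    i, j = divmod(flat, H.shape[1])
    return score, i, j


def backtrack(
    mats: DPMatrices,
    p: Sequence,
    q: Sequence,
    scheme: ScoringScheme,
    start,
    policy: BacktrackPolicy = BacktrackPolicy(),
) -> AlignmentResult:
    """Reconstruct the alignment ending at ``start = (i, j)``.

    Walks the cell each value was computed from -- diagonally on a
    substitution, up through the F (gap-in-target) state, left through the
    E (gap-in-query) state -- until a cell with H at or below the policy
    threshold, or the matrix border, is reached.  The reconstructed gapped
    pair re-scores exactly to ``H[start]``.
    """
    H, E, F = mats.H, mats.E, mats.F
    i, j = start
    if not (0 <= i < H.shape[0] and 0 <= j < H.shape[1]):
        raise IndexError(f"start {start} outside matrix of shape {H.shape}")
    end_i, end_j = i, j
    score = int(H[i, j])
    ap: list = []  # query column, reversed
    at: list = []  # target column, reversed
    state = "H"
    goe, ge = scheme.gap_open_extend, scheme.gap_extend
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] <= policy.threshold:
                break
            moved = False
            for move in policy.tie_order:
                if move == "diagonal":
                    s = substitution_score(
                        p.residues[i - 1], q.residues[j - 1], scheme, p.alphabet
                    )
                    if H[i, j] == H[i - 1, j - 1] + s:
                        ap.append(p.residues[i - 1])
                        at.append(q.residues[j - 1])
                        i -= 1
                        j -= 1
                        moved = True
                        break
                elif move == "up":
                    if H[i, j] == F[i, j]:
                        state = "F"
                        moved = True
                        break
                else:  # left
                    if H[i, j] == E[i, j]:
                        state = "E"
                        moved = True
                        break
            if not moved:  # H[i, j] == 0 handled above; defensive
                break
        elif state == "F":
            ap.append(p.residues[i - 1])
            at.append("-")
            if F[i, j] == H[i - 1, j] - goe:
                state = "H"
            i -= 1
        else:  # state == "E"
            ap.append("-")
            at.append(q.residues[j - 1])
            if E[i, j] == H[i, j - 1] - goe:
                state = "H"
            j -= 1
    aligned_query = "".join(reversed(ap))
    aligned_target = "".join(reversed(at))
    if not aligned_query:
        return _empty_result()
    return AlignmentResult(
        score=score,
        query_start=i + 1,
        query_end=end_i,
        target_start=j + 1,
        target_end=end_j,
        aligned_query=aligned_query,
        aligned_target=aligned_target,
        cigar=cigar_string(aligned_query, aligned_target),
    )


def _empty_result() -> AlignmentResult:
    return AlignmentResult(0, 0, 0, 0, 0, "", "", "")


def cigar_string(aligned_query: str, aligned_target: str) -> str:
    """Run-length CIGAR over M (both residues), I (gap in target),
    D (gap in query)."""
    if len(aligned_query) != len(aligned_target):
        raise ValueError("gapped strings must have equal length")
    ops = []
    for a, b in zip(aligned_query, aligned_target):
        if a != "-" and b != "-":
            ops.append("M")
        elif b == "-":
            ops.append("I")
        elif a == "-":
            ops.append("D")
        else:
            raise ValueError("gap aligned to gap")
    out = []
    k = 0
    while k < len(ops):
        r = k
        while r < len(ops) and ops[r] == ops[k]:
            r += 1
        out.append(f"{r - k}{ops[k]}")
        k = r
    return "".join(out)


def rescore_alignment(
    aligned_query: str, aligned_target: str, scheme: ScoringScheme, alphabet: str = DNA_ALPHABET
) -> int:
    """Re-score a gapped pair under the scheme.

    A gap run of length L costs Goe + (L-1)*Ge (in linear mode Goe == Ge,
    i.e. a constant cost per gapped position).
    """
    if len(aligned_query) != len(aligned_target):
        raise ValueError("gapped strings must have equal length")
    total = 0
    in_gap_q = in_gap_t = False
    for a, b in zip(aligned_query, aligned_target):
        if a == "-" and b == "-":
            raise ValueError("gap aligned to gap")
        if a == "-":
            total -= scheme.gap_extend if in_gap_q else scheme.gap_open_extend
            in_gap_q, in_gap_t = True, False
        elif b == "-":
            total -= scheme.gap_extend if in_gap_t else scheme.gap_open_extend
            in_gap_q, in_gap_t = False, True
        else:
            total += substitution_score(a, b, scheme, alphabet)
            in_gap_q = in_gap_t = False
    return total


def align_serial(
    p: Sequence,
    q: Sequence,
    scheme: ScoringScheme,
    policy: BacktrackPolicy = BacktrackPolicy(),
    score_only: bool = False,
) -> AlignmentResult:
    """Serial pairwise local alignment: fill, locate the maximum, backtrack.

    With ``score_only`` the kernel runs in O(min-side) memory and reports
    the score and end coordinates only (start coordinates 0, CIGAR ``*``).
    """
    _check_pair_alphabet(p, q)
    if score_only:
        best, bi, bj = _score_only_rolling(
            p.codes,
            q.codes,
            scheme.match_score,
            scheme.mismatch_score,
            scheme.gap_open_extend,
            scheme.gap_extend,
            p.ambiguity_code,
        )
        if best == 0:
            return _empty_result()
        return AlignmentResult(int(best), 0, int(bi), 0, int(bj), "", "", "*")
    mats = fill_matrices(p, q, scheme)
    score, i, j = find_max(mats)
    if i is None:
        return _empty_result()
    return backtrack(mats, p, q, scheme, (i, j), policy)
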