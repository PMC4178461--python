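"""Exact global pairwise alignment under an edit-distance-equivalent penalty system.

Instead of maximizing a Needleman-Wunsch similarity score, the aligner
minimizes a system of non-negative integer penalties (match 0, mismatch > 0,
affine gaps) obtained by an exact transformation of the similarity scheme.
For a global alignment of sequences of lengths m and n,

    2 * similarity_score = match * (m + n) - doubled_penalty,

where the doubled penalty charges 2*(match - mismatch) per mismatch column,
2*|gap_open| per gap, and match + 2*|gap_extend| per gap column.  Minimizing
the doubled penalty is therefore strictly equivalent to maximizing the
similarity score: the two systems admit exactly the same optimal alignments.
The *number of differences* between two amplicons is the count of mismatch
and indel columns in one optimal alignment.

Under the default scoring (match +5, mismatch -4, gap open -12, gap extend
-4) the transformed penalties are mismatch 9, gap opening 12 and gap
extension 7 on the half scale (the exact half-scale extension cost is 6.5;
optimality is always decided on the fraction-free doubled scale 18/24/13).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from ._encoding import encode_sequence

__all__ = [
    "ScoringSystem",
    "PenaltySystem",
    "AlignmentResult",
    "transform_scoring",
    "align",
    "count_differences",
    "max_differences_in_byte",
    "DEFAULT_SCORING",
    "DEFAULT_PENALTIES",
]


@dataclass(frozen=True)
class ScoringSystem:
    """Similarity scoring scheme (rewards positive, penalties negative)."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -4

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be below the match reward")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap scores must be <= 0")


@dataclass(frozen=True)
class PenaltySystem:
    """Non-negative integer penalty system equivalent to a similarity scheme.

    ``doubled`` holds the fraction-free costs actually used by the dynamic
    program (per-mismatch, per-gap opening, per-gap-column extension on twice
    the half scale).  When a system is built directly from integer penalties
    the doubled costs are exactly twice the stated ones; systems produced by
    :func:`transform_scoring` carry the exact doubled costs, which may differ
    from twice the rounded half-scale extension penalty.
    """

    mismatch_penalty: int = 9
    gap_open_penalty: int = 12
    gap_extend_penalty: int = 7
    doubled: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if self.mismatch_penalty <= 0:
            raise ValueError("mismatch penalty must be positive")
        if self.gap_open_penalty < 0 or self.gap_extend_penalty < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.doubled is None:
            object.__setattr__(
                self,
                "doubled",
                (
                    2 * self.mismatch_penalty,
                    2 * self.gap_open_penalty,
                    2 * self.gap_extend_penalty,
                ),
            )


def transform_scoring(scoring: ScoringSystem) -> PenaltySystem:
    """Transform a similarity scheme into the equivalent penalty system.

    Half-scale penalties: mismatch = match - mismatch score, gap opening =
    |gap_open|, gap extension = (match + 2*|gap_extend|) / 2 rounded half up.
    The exact doubled-scale costs are retained for the dynamic program so the
    optimal-alignment sets of the two systems are strictly identical.
    """
    mismatch2 = 2 * (scoring.match - scoring.mismatch)
    open2 = 2 * abs(scoring.gap_open)
    extend2 = scoring.match + 2 * abs(scoring.gap_extend)
    return PenaltySystem(
        mismatch_penalty=mismatch2 // 2,
        gap_open_penalty=open2 // 2,
        gap_extend_penalty=(extend2 + 1) // 2,  # round half up, e.g. 6.5 -> 7
        doubled=(mismatch2, open2, extend2),
    )


DEFAULT_SCORING = ScoringSystem()
DEFAULT_PENALTIES = transform_scoring(DEFAULT_SCORING)

# Alignment column operations emitted by the backtracker.
_OP_MATCH = 0  # M: aligned identical bases
_OP_MISMATCH = 1  # X: aligned differing bases
_OP_DEL = 2  # D: consumes a residue of the first sequence only
_OP_INS = 3  # I: consumes a residue of the second sequence only
_OP_CHARS = "MXDI"


@njit(cache=True)
def _gotoh_ops(a, b, mismatch2, open2, extend2):  # pragma: no cover - jitted
    """Three-state affine minimization with deterministic backtracking.

    Returns the column operations of one optimal alignment, terminal cell
    first (caller reverses).  Co-optimal ties are broken by preferring the
    diagonal move, then a gap in the second sequence (D), then a gap in the
    first (I); within a gap state, closing the gap is preferred over
    extending it.
    """
    m = a.shape[0]
    n = b.shape[0]
    big = np.int32(1 << 29)
    gap1 = np.int32(open2 + extend2)
    ext = np.int32(extend2)
    mis = np.int32(mismatch2)

    H = np.empty((m + 1, n + 1), np.int32)
    E = np.empty((m + 1, n + 1), np.int32)  # gap in b (vertical, D)
    F = np.empty((m + 1, n + 1), np.int32)  # gap in a (horizontal, I)
    H[0, 0] = 0
    E[0, 0] = big
    F[0, 0] = big
    for i in range(1, m + 1):
        E[i, 0] = gap1 + ext * (i - 1)
        H[i, 0] = E[i, 0]
        F[i, 0] = big
    for j in range(1, n + 1):
        F[0, j] = gap1 + ext * (j - 1)
        H[0, j] = F[0, j]
        E[0, j] = big
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i - 1, j] + gap1
            t = E[i - 1, j] + ext
            if t < e:
                e = t
            f = H[i, j - 1] + gap1
            t = F[i, j - 1] + ext
            if t < f:
                f = t
            if ai == b[j - 1]:
                s = H[i - 1, j - 1]
            else:
                s = H[i - 1, j - 1] + mis
            h = s
            if e < h:
                h = e
            if f < h:
                h = f
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h

    ops = np.empty(m + n, np.uint8)
    k = 0
    i = m
    j = n
    state = 0  # 0 = H, 1 = E (emitting D), 2 = F (emitting I)
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0:
                if a[i - 1] == b[j - 1]:
                    s = H[i - 1, j - 1]
                    op = np.uint8(0)
                else:
                    s = H[i - 1, j - 1] + mis
                    op = np.uint8(1)
                if H[i, j] == s:
                    ops[k] = op
                    k += 1
                    i -= 1
                    j -= 1
                    continue
            if i > 0 and H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            close = H[i - 1, j] + gap1
            cur = E[i, j]
            i -= 1
            if cur == close:
                state = 0
        else:
            ops[k] = 3
            k += 1
            close = H[i, j - 1] + gap1
            cur = F[i, j]
            j -= 1
            if cur == close:
                state = 0
    return ops[:k]


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal global alignment and its summary statistics.

    ``differences`` counts mismatch and indel columns; ``penalty_score`` is
    the half-scale penalty decomposition of the returned alignment
    (mismatch_penalty per X column plus, per gap, gap_open_penalty +
    gap_extend_penalty * gap length).
    """

    penalty_score: int
    cigar: str
    differences: int
    matches: int
    alignment_length: int


def _ops_to_result(ops: np.ndarray, penalties: PenaltySystem) -> AlignmentResult:
    ops = ops[::-1]
    n_match = int(np.count_nonzero(ops == _OP_MATCH))
    n_mismatch = int(np.count_nonzero(ops == _OP_MISMATCH))
    # Run-length encode for the CIGAR and per-gap penalty accounting.
    parts: list[str] = []
    score = penalties.mismatch_penalty * n_mismatch
    n_indel = 0
    i = 0
    total = ops.size
    while i < total:
        op = ops[i]
        j = i
        while j < total and ops[j] == op:
            j += 1
        run = j - i
        parts.append(f"{run}{_OP_CHARS[op]}")
        if op in (_OP_DEL, _OP_INS):
            score += penalties.gap_open_penalty + penalties.gap_extend_penalty * run
            n_indel += run
        i = j
    return AlignmentResult(
        penalty_score=score,
        cigar="".join(parts),
        differences=n_mismatch + n_indel,
        matches=n_match,
        alignment_length=total,
    )


def align(a: str, b: str, penalties: PenaltySystem | None = None) -> AlignmentResult:
    """Globally align two normalized DNA sequences, minimizing total penalty."""
    if penalties is None:
        penalties = DEFAULT_PENALTIES
    ops = _gotoh_ops(encode_sequence(a), encode_sequence(b), *penalties.doubled)
    return _ops_to_result(ops, penalties)


def count_differences(a: str, b: str, penalties: PenaltySystem | None = None) -> int:
    """Number of mismatches and indel columns in an optimal global alignment."""
    return align(a, b, penalties).differences


def count_differences_encoded(
    a_codes: np.ndarray, b_codes: np.ndarray, penalties: PenaltySystem
) -> int:
    """Difference count on pre-encoded sequences (hot path for clustering)."""
    ops = _gotoh_ops(a_codes, b_codes, *penalties.doubled)
    return int(np.count_nonzero(ops))


def max_differences_in_byte(
    penalties: PenaltySystem | None = None, byte_max: int = 255
) -> int:
    """Largest difference count whose cheapest possible penalty fits in a byte.

    The cheapest single difference costs min(mismatch, one-column gap);
    an unsigned byte bounds scores at 255, which caps the number of
    differences representable in 8-bit score arithmetic.
    """
    if penalties is None:
        penalties = DEFAULT_PENALTIES
    per_difference = min(
        penalties.mismatch_penalty,
        penalties.gap_open_penalty + penalties.gap_extend_penalty,
    )
    return byte_max // per_difference
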