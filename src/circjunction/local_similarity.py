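"""Local-similarity test for candidate BSJ read pairs.

Any two reads spanning the same back-spliced junction share an overlapping
subsequence (the "local similar sequence"): both contain donor-side bases
followed by acceptor-side bases around the junction point.  The optimal
local alignment between the two read sequences is computed by affine-gap
Smith-Waterman dynamic programming; a pair is accepted when the similar
region is long enough, contains few mismatches and gap columns, and spans
the clip boundary (the junction point) of *both* reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution and affine gap scores.

    A gap run of length k costs ``gap_open + (k - 1) * gap_extend``; N never
    matches anything and scores as a mismatch.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass
class LocalAlignmentResult:
    """An optimal local alignment between two reads.

    Intervals are 1-based inclusive on the input sequences; a zero score
    comes with empty intervals and empty gapped strings.  ``gaps`` counts
    gap columns (dashes), not gap runs.
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    mismatches: int
    gaps: int
    aligned_a: str
    aligned_b: str

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


@njit(cache=False)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -(10**8), dtype=np.int32)  # gap in a (left)
    F = np.full((n + 1, m + 1), -(10**8), dtype=np.int32)  # gap in b (up)
    # H pointer: 0 stop, 1 diag, 2 up (F), 3 left (E)
    HP = np.zeros((n + 1, m + 1), dtype=np.uint8)
    # E/F pointer: 1 opened from H, 0 extended
    EP = np.zeros((n + 1, m + 1), dtype=np.uint8)
    FP = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                EP[i, j] = 1
            else:
                E[i, j] = e_ext
                EP[i, j] = 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                FP[i, j] = 1
            else:
                F[i, j] = f_ext
                FP[i, j] = 0
            if ai == b[j - 1] and ai < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            # preference: diagonal > up > left > stop
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            HP[i, j] = p
            if h > best:
                best = h
                best_i = i
                best_j = j
    return best, best_i, best_j, HP, EP, FP


def local_align(seq_a: str, seq_b: str, scoring: ScoringScheme = ScoringScheme()) -> LocalAlignmentResult:
    """Optimal local (Smith-Waterman) alignment of two nucleotide strings.

    Deterministic among co-optimal alignments: the end cell with the highest
    score and smallest (a, b) coordinates is chosen, and traceback prefers
    diagonal over vertical over horizontal moves, which selects the smallest
    (a_start, b_start) representative.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = _ENCODE[np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)]
    b = _ENCODE[np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)]
    score, i, j, HP, EP, FP = _sw_fill(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score <= 0:
        return LocalAlignmentResult(0, 0, 0, 0, 0, 0, 0, "", "")
    end_i, end_j = i, j
    cols_a: list[str] = []
    cols_b: list[str] = []
    mismatches = 0
    gaps = 0
    state = "H"
    while True:
        if state == "H":
            p = HP[i, j]
            if p == 0:
                break
            if p == 1:
                cols_a.append(seq_a[i - 1])
                cols_b.append(seq_b[j - 1])
                if seq_a[i - 1].upper() != seq_b[j - 1].upper() or seq_a[i - 1].upper() == "N":
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols_a.append(seq_a[i - 1])
            cols_b.append("-")
            gaps += 1
            opened = FP[i, j] == 1
            i -= 1
            if opened:
                state = "H"
        else:  # E
            cols_a.append("-")
            cols_b.append(seq_b[j - 1])
            gaps += 1
            opened = EP[i, j] == 1
            j -= 1
            if opened:
                state = "H"
    return LocalAlignmentResult(
        score=int(score),
        a_start=i + 1,
        a_end=end_i,
        b_start=j + 1,
        b_end=end_j,
        mismatches=mismatches,
        gaps=gaps,
        aligned_a="".join(reversed(cols_a)),
        aligned_b="".join(reversed(cols_b)),
    )


def spans_junction(result: LocalAlignmentResult, left, right) -> bool:
    """Does the similar region cross the clip boundary of both reads?

    The left read's junction point sits between positions ``left_clip`` and
    ``left_clip + 1``; the right read's between ``len - right_clip`` and the
    next base.  The aligned interval must include bases on both sides of
    each boundary.
    """
    if result.score <= 0 or result.columns == 0:
        return False
    lb = left.left_clip
    if not (result.a_start <= lb and result.a_end >= lb + 1):
        return False
    rb = len(right.sequence) - right.right_clip
    return result.b_start <= rb and result.b_end >= rb + 1


def mismatch_threshold(read_len: int, rate: float = 0.02) -> int:
    """Read-length-scaled default mismatch/gap threshold (2 per 100 bp)."""
    return max(1, math.ceil(rate * read_len))


def accept_pair(
    pair,
    scoring: ScoringScheme = ScoringScheme(),
    max_mismatch: int = 2,
    max_gap: int = 2,
    min_overlap: int = 15,
) -> bool:
    """Putative-BSJ decision for a candidate pair.

    True iff the optimal local alignment of the two read sequences covers at
    least ``min_overlap`` columns with at most ``max_mismatch`` mismatches
    and ``max_gap`` gap columns, and spans both reads' junction points.
    """
    res = local_align(pair.left.sequence, pair.right.sequence, scoring)
    if res.columns < min_overlap:
        return False
    if res.mismatches > max_mismatch or res.gaps > max_gap:
        return False
    return spans_junction(res, pair.left, pair.right)
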