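"""Affine-gap local alignment (Gotoh-style Smith-Waterman), NumPy-accelerated.

This is the package's own replacement for an external BLAST-style engine:
optimal local alignment under match/mismatch scores and affine gap costs,
with a full traceback giving matches, alignment columns and gap runs. For
long targets the optimal end cell is located with a memory-light scoring
scan and the traceback is recovered inside a provably sufficient window
around it, so full genomes can be aligned without quadratic memory.

Conventions
-----------
* Scores: ``match > 0``, ``mismatch <= 0``; a gap of length L costs
  ``gap_open + (L - 1) * gap_extend`` with ``gap_open <= gap_extend < 0``.
* Coordinates are 0-based half-open.
* Equal-score ties resolve to the lowest alignment end on the target, then
  the lowest end on the query, with a diagonal-preferring traceback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

NEG_INF = np.int32(-(2**30))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """blastn-flavoured integer scoring; see module docstring for the
    gap-cost convention."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise AlignmentError("match reward must be positive")
        if self.mismatch > 0:
            raise AlignmentError("mismatch penalty must be <= 0")
        if not (self.gap_open <= self.gap_extend < 0):
            raise AlignmentError(
                "require gap_open <= gap_extend < 0 "
                "(gap of length L costs gap_open + (L-1)*gap_extend)"
            )


#: default blastn-like scheme (favours >=60% identity homologs, as a
#: megablast-style screen would)
DEFAULT_SCORING = ScoringScheme()

#: permissive scheme for distant homologs: positive expected score down to
#: ~34% identity, so alignments at the 50% presence threshold still extend
#: over the full query
SENSITIVE_SCORING = ScoringScheme(match=2, mismatch=-1,
                                  gap_open=-5, gap_extend=-2)


@dataclass(frozen=True)
class Alignment:
    """Best local alignment of query vs target (forward orientations)."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    align_cols: int
    #: ordered runs of gap columns: ("ins", L) = L target bases absent from
    #: the query; ("del", L) = L query bases absent from the target
    gap_runs: tuple[tuple[Literal["ins", "del"], int], ...]

    @property
    def inserted_bases(self) -> int:
        return sum(n for kind, n in self.gap_runs if kind == "ins")

    @property
    def deleted_bases(self) -> int:
        return sum(n for kind, n in self.gap_runs if kind == "del")

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.align_cols if self.align_cols else 0.0

    def coverage_pct(self, query_length: int) -> float:
        return 100.0 * (self.q_end - self.q_start) / query_length


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3; reject anything else."""
    if not seq:
        raise AlignmentError("empty sequence")
    arr = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq.upper()) - set("ACGT"))
        raise AlignmentError(f"non-ACGT characters in sequence: {bad}")
    return arr


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _score_scan(q: np.ndarray, t: np.ndarray, sc: ScoringScheme):
    """Best local score and its end cell, O(len(t)) memory.

    Returns (score, i_end, j_end) where the alignment ends at query index
    i_end (exclusive) and target index j_end (exclusive).
    """
    m, n = q.size, t.size
    match, mismatch = np.int32(sc.match), np.int32(sc.mismatch)
    go, ge = np.int32(sc.gap_open), np.int32(sc.gap_extend)

    h_prev = np.zeros(n + 1, dtype=np.int32)
    f = np.full(n + 1, NEG_INF, dtype=np.int32)
    jj = np.arange(n + 1, dtype=np.int64)
    best, best_i, best_j = 0, 0, 0
    h_full = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        s = np.where(t == q[i - 1], match, mismatch)
        np.maximum(h_prev[1:] + go, f[1:] + ge, out=f[1:])
        h_hat = np.maximum(0, np.maximum(h_prev[:-1] + s, f[1:]))
        # horizontal (target-insertion) gaps via prefix-max closed form
        h_full[0] = 0
        h_full[1:] = h_hat
        p = h_full - ge * jj.astype(np.int32)
        c = np.maximum.accumulate(p)
        e = go + ge * (jj[1:].astype(np.int32) - 1) + c[:-1]
        row = np.maximum(h_hat, e)
        j_arg = int(np.argmax(row))
        row_best = int(row[j_arg])
        if row_best > best or (
            row_best == best and best > 0 and (j_arg + 1, i) < (best_j, best_i)
        ):
            best, best_i, best_j = row_best, i, j_arg + 1
        h_prev[1:] = row
    return best, best_i, best_j


_PTR_STOP, _PTR_DIAG, _PTR_E, _PTR_F = 0, 1, 2, 3


def _dp_traceback(q: np.ndarray, t: np.ndarray,
                  sc: ScoringScheme) -> Alignment:
    """Full-matrix local DP with traceback; quadratic memory (windows only)."""
    m, n = q.size, t.size
    match, mismatch = np.int32(sc.match), np.int32(sc.mismatch)
    go, ge = np.int32(sc.gap_open), np.int32(sc.gap_extend)

    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptr_e_ext = np.zeros((m + 1, n + 1), dtype=bool)
    ptr_f_ext = np.zeros((m + 1, n + 1), dtype=bool)

    f = np.full(n + 1, NEG_INF, dtype=np.int32)
    jj = np.arange(n + 1, dtype=np.int32)
    h_full = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        h_prev = H[i - 1]
        s = np.where(t == q[i - 1], match, mismatch)
        f_open = h_prev[1:] + go
        f_ext = f[1:] + ge
        f[1:] = np.maximum(f_open, f_ext)
        ptr_f_ext[i, 1:] = f_ext > f_open
        diag = h_prev[:-1] + s
        h_hat = np.maximum(0, np.maximum(diag, f[1:]))
        h_full[0] = 0
        h_full[1:] = h_hat
        p = h_full - ge * jj
        c = np.maximum.accumulate(p)
        e = go + ge * (jj[1:] - 1) + c[:-1]
        row = np.maximum(h_hat, e)
        # pointer bookkeeping (diagonal preferred, then E, then F)
        ptr = np.zeros(n, dtype=np.uint8)
        ptr[(row > 0) & (row == f[1:])] = _PTR_F
        ptr[(row > 0) & (row == e)] = _PTR_E
        ptr[(row > 0) & (row == diag)] = _PTR_DIAG
        ptr_h[i, 1:] = ptr
        # E came either by opening from H[i, j-1] or extending E[i, j-1]
        e_shift = np.empty(n, dtype=np.int32)
        e_shift[0] = NEG_INF
        e_shift[1:] = e[:-1]
        h_left = np.empty(n, dtype=np.int32)
        h_left[0] = 0
        h_left[1:] = row[:-1]
        ptr_e_ext[i, 1:] = (e_shift + ge) > (h_left + go)
        H[i, 1:] = row

    best = int(H.max())
    if best <= 0:
        return Alignment(0, 0, 0, 0, 0, 0, 0, ())
    cand = np.argwhere(H == best)
    # lowest end on target, then lowest end on query
    order = np.lexsort((cand[:, 0], cand[:, 1]))
    i, j = (int(x) for x in cand[order[0]])

    q_end, t_end = i, j
    matches = 0
    cols = 0
    gap_runs: list[tuple[str, int]] = []
    state = _PTR_DIAG  # meaning: currently in H
    in_h = True
    while True:
        if in_h:
            move = ptr_h[i, j]
            if move == _PTR_STOP:
                break
            if move == _PTR_DIAG:
                cols += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif move == _PTR_E:
                in_h = False
                state = _PTR_E
            else:
                in_h = False
                state = _PTR_F
        elif state == _PTR_E:
            # horizontal run: target bases inserted relative to the query
            run = 1
            while ptr_e_ext[i, j] and j > 1:
                run += 1
                j -= 1
            j -= 1
            cols += run
            gap_runs.append(("ins", run))
            in_h = True
        else:
            run = 1
            while ptr_f_ext[i, j] and i > 1:
                run += 1
                i -= 1
            i -= 1
            cols += run
            gap_runs.append(("del", run))
            in_h = True
    gap_runs.reverse()
    return Alignment(
        score=best, q_start=i, q_end=q_end, t_start=j, t_end=t_end,
        matches=matches, align_cols=cols,
        gap_runs=tuple(gap_runs),  # type: ignore[arg-type]
    )


def _window_bound(m: int, sc: ScoringScheme) -> int:
    """Max target span of any positive-score local alignment of a length-m
    query: matches can pay for at most m*match/|gap_extend| gap columns."""
    return m + int(np.ceil(m * sc.match / abs(sc.gap_extend))) + 2


# targets up to this length get the exact full-matrix DP directly
_FULL_DP_LIMIT = 8192


def local_align(
    query: str | np.ndarray,
    target: str | np.ndarray,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> Alignment:
    """Optimal affine-gap local alignment of ``query`` against ``target``.

    Both sequences are plus-strand as given; strand handling lives in
    :mod:`hmoscreen.screen`. Raises on empty or non-ACGT input.
    """
    q = query if isinstance(query, np.ndarray) else encode(query)
    t = target if isinstance(target, np.ndarray) else encode(target)
    if t.size <= _FULL_DP_LIMIT or t.size <= _window_bound(q.size, scoring):
        return _dp_traceback(q, t, scoring)

    score, _, j_end = _score_scan(q, t, scoring)
    if score <= 0:
        return Alignment(0, 0, 0, 0, 0, 0, 0, ())
    w_start = max(0, j_end - _window_bound(q.size, scoring))
    aln = _dp_traceback(q, t[w_start:j_end], scoring)
    if aln.score != score:  # pragma: no cover - defensive
        raise AssertionError("windowed traceback lost the optimal alignment")
    return Alignment(
        score=aln.score,
        q_start=aln.q_start, q_end=aln.q_end,
        t_start=aln.t_start + w_start, t_end=aln.t_end + w_start,
        matches=aln.matches, align_cols=aln.align_cols,
        gap_runs=aln.gap_runs,
    )


def max_subarray_score(equal: np.ndarray, sc: ScoringScheme) -> int:
    """Best ungapped segment score for a boolean match profile (Kadane,
    vectorized); used by the seed-and-extend filter in the search layer."""
    s = np.where(equal, sc.match, sc.mismatch).astype(np.int64)
    c = np.cumsum(s)
    running_min = np.minimum.accumulate(np.concatenate(([0], c[:-1])))
    return max(0, int(np.max(c - running_min)))
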