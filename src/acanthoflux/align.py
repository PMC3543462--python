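"""Exact global pairwise alignment (Needleman–Wunsch, affine gaps).

Alignments are end-to-end: terminal gaps are penalized like internal ones.
A gap of length L costs ``gap_open + (L-1) * gap_extend`` (the opening
penalty covers the first gapped base).  Traceback is deterministic with tie
order diagonal > up > left, so alignments are reproducible byte-for-byte.

Percent identity is the fraction of alignment columns in which both symbols
are the same A/C/G/T; columns containing N, another ambiguity code, or a
gap count in the denominator only.  Identity is returned as an exact
``fractions.Fraction`` so that ties between references can be detected
without floating-point artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numba import njit

NEG_INF = np.iinfo(np.int64).min // 4

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and every other symbol (N, IUPAC codes) to 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap DNA scoring; defaults are common global-search values."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal global alignment with its score and identity."""

    aligned_query: str
    aligned_ref: str
    score: int
    n_matches: int
    n_columns: int

    @property
    def identity(self) -> Fraction:
        return Fraction(self.n_matches, self.n_columns)


# DP states: 0 = M (diagonal), 1 = Ix (gap in ref, consumes query; "up"),
# 2 = Iy (gap in query, consumes ref; "left").  Pointer matrices store the
# predecessor state chosen under the preference order M > Ix > Iy.


@njit(cache=True)
def _nw_fill(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(r)
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
        ptrX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
        ptrY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            # M: best predecessor at (i-1, j-1), preference M > Ix > Iy
            best = M[i - 1, j - 1]
            state = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                state = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                state = 2
            M[i, j] = best + s
            ptrM[i, j] = state
            # Ix: consume query base i against a gap
            best = M[i - 1, j] + gap_open
            state = 0
            if Ix[i - 1, j] + gap_extend > best:
                best = Ix[i - 1, j] + gap_extend
                state = 1
            if Iy[i - 1, j] + gap_open > best:
                best = Iy[i - 1, j] + gap_open
                state = 2
            Ix[i, j] = best
            ptrX[i, j] = state
            # Iy: consume ref base j against a gap
            best = M[i, j - 1] + gap_open
            state = 0
            if Ix[i, j - 1] + gap_open > best:
                best = Ix[i, j - 1] + gap_open
                state = 1
            if Iy[i, j - 1] + gap_extend > best:
                best = Iy[i, j - 1] + gap_extend
                state = 2
            Iy[i, j] = best
            ptrY[i, j] = state
    return M, Ix, Iy, ptrM, ptrX, ptrY


@njit(cache=True)
def _nw_score_only(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Linear-memory variant returning (score, n_matches, n_columns) of the
    traceback-preferred optimal alignment is not derivable without pointers,
    so this returns the optimal score only; used for fast screening."""
    n, m = len(q), len(r)
    M = np.full(m + 1, NEG_INF, dtype=np.int64)
    Ix = np.full(m + 1, NEG_INF, dtype=np.int64)
    Iy = np.full(m + 1, NEG_INF, dtype=np.int64)
    M[0] = 0
    for j in range(1, m + 1):
        Iy[j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        qi = q[i - 1]
        diagM, diagX, diagY = M[0], Ix[0], Iy[0]
        M[0] = NEG_INF
        Ix[0] = gap_open + (i - 1) * gap_extend
        Iy[0] = NEG_INF
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            newM = diagM
            if diagX > newM:
                newM = diagX
            if diagY > newM:
                newM = diagY
            newM += s
            newX = M[j] + gap_open
            if Ix[j] + gap_extend > newX:
                newX = Ix[j] + gap_extend
            if Iy[j] + gap_open > newX:
                newX = Iy[j] + gap_open
            diagM, diagX, diagY = M[j], Ix[j], Iy[j]
            M[j] = newM
            Ix[j] = newX
            newY = M[j - 1] + gap_open
            if Ix[j - 1] + gap_open > newY:
                newY = Ix[j - 1] + gap_open
            if Iy[j - 1] + gap_extend > newY:
                newY = Iy[j - 1] + gap_extend
            Iy[j] = newY
    best = M[m]
    if Ix[m] > best:
        best = Ix[m]
    if Iy[m] > best:
        best = Iy[m]
    return best


@njit(cache=True)
def _nw_traceback(q, r, M, Ix, Iy, ptrM, ptrX, ptrY):  # pragma: no cover
    n, m = len(q), len(r)
    # final state preference: M > Ix > Iy
    state = 0
    best = M[n, m]
    if Ix[n, m] > best:
        best = Ix[n, m]
        state = 1
    if Iy[n, m] > best:
        best = Iy[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = ptrM[i, j]
            ops[k] = 0
            i -= 1
            j -= 1
        elif state == 1:
            prev = ptrX[i, j]
            ops[k] = 1
            i -= 1
        else:
            prev = ptrY[i, j]
            ops[k] = 2
            j -= 1
        k += 1
        state = prev
    return best, ops[:k][::-1]


def global_align(
    query: str, ref: str, scoring: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences over {A,C,G,T,N}.

    Raises ``ValueError`` on empty input.  N (and any other ambiguity
    symbol) scores as a mismatch against everything, including itself.
    """
    if not query or not ref:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or ScoringScheme()
    q = encode_sequence(query)
    r = encode_sequence(ref)
    tables = _nw_fill(
        q, r, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    score, ops = _nw_traceback(q, r, *tables)
    aq_parts: list[str] = []
    ar_parts: list[str] = []
    qi = ri = 0
    n_matches = 0
    for op in ops:
        if op == 0:
            cq, cr = query[qi], ref[ri]
            if cq == cr and q[qi] < 4:
                n_matches += 1
            aq_parts.append(cq)
            ar_parts.append(cr)
            qi += 1
            ri += 1
        elif op == 1:
            aq_parts.append(query[qi])
            ar_parts.append("-")
            qi += 1
        else:
            aq_parts.append("-")
            ar_parts.append(ref[ri])
            ri += 1
    return PairwiseAlignment(
        aligned_query="".join(aq_parts),
        aligned_ref="".join(ar_parts),
        score=int(score),
        n_matches=n_matches,
        n_columns=len(ops),
    )


def global_align_score(
    query: str, ref: str, scoring: ScoringScheme | None = None
) -> int:
    """Optimal global alignment score only (linear memory, no traceback)."""
    if not query or not ref:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or ScoringScheme()
    return int(
        _nw_score_only(
            encode_sequence(query),
            encode_sequence(ref),
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
        )
    )


def percent_identity(aln: PairwiseAlignment) -> Fraction:
    """Identity as matches over all alignment columns, as an exact rational."""
    if aln.n_columns == 0:
        raise ValueError("alignment has no columns")
    return Fraction(aln.n_matches, aln.n_columns)
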