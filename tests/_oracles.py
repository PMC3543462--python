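"""Independent oracles used by the test suite.

The brute-force aligner enumerates every global alignment of two short
sequences as a sequence of match/up/left moves, scoring gap runs with the
affine convention (open covers the first gapped base, extend each further
one).  It shares no code with the dynamic-programming implementation.
"""

from __future__ import annotations

from acanthoflux.align import ScoringScheme


def brute_force_global_score(q: str, r: str, sc: ScoringScheme) -> int:
    """Maximum score over all global alignments, by exhaustive enumeration.

    Feasible for len(q), len(r) <= ~8; exponential beyond that.
    """
    best = [None]

    def rec(i: int, j: int, prev: str, score: int) -> None:
        if i == len(q) and j == len(r):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(q) and j < len(r):
            a, b = q[i].upper(), r[j].upper()
            s = sc.match if (a == b and a in "ACGT") else sc.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(q):
            pen = sc.gap_extend if prev == "U" else sc.gap_open
            rec(i + 1, j, "U", score + pen)
        if j < len(r):
            pen = sc.gap_extend if prev == "L" else sc.gap_open
            rec(i, j + 1, "L", score + pen)

    rec(0, 0, "", 0)
    return best[0]
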