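"""Independent brute-force oracles used by the test suite.

The Smith-Waterman here is a plain full-matrix Gotoh implementation written
directly from the recurrences, sharing no code with the package's seeded,
banded engine.  Gap convention: a gap of length g costs open + g * extend.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def sw_score(q: str, t: str, submat, alphabet: str, gap_open: int = 11,
             gap_extend: int = 1) -> int:
    """Optimal local alignment raw score by exhaustive dynamic programming."""
    qi = [alphabet.index(c) for c in q]
    ti = [alphabet.index(c) for c in t]
    m, n = len(qi), len(ti)
    oc = gap_open + gap_extend
    best = 0
    H_prev = [0.0] * (n + 1)
    F_prev = [NEG] * (n + 1)
    for i in range(1, m + 1):
        H_cur = [0.0] * (n + 1)
        F_cur = [NEG] * (n + 1)
        E = NEG
        for j in range(1, n + 1):
            F_cur[j] = max(H_prev[j] - oc, F_prev[j] - gap_extend)
            E = max(H_cur[j - 1] - oc, E - gap_extend)
            diag = H_prev[j - 1] + submat[qi[i - 1]][ti[j - 1]]
            H_cur[j] = max(0.0, diag, E, F_cur[j])
            if H_cur[j] > best:
                best = H_cur[j]
        H_prev, F_prev = H_cur, F_cur
    return int(best)


def bit_score(raw: float, lam: float = 0.267, k: float = 0.041) -> float:
    return (lam * raw - math.log(k)) / math.log(2)


def best_translated_score(read: str, targets, submat, alphabet: str,
                          translate) -> float:
    """Best raw score of any frame against any target, exhaustively."""
    best = 0
    for pep in translate(read):
        for t in targets:
            s = sw_score(pep, t, submat, alphabet)
            if s > best:
                best = s
    return best


def simplex_grid(n: int, step: float = 0.05):
    """All points of the n-simplex on a regular grid (used as the weight
    optimizer's independent oracle at small n)."""
    k = round(1.0 / step)

    def rec(prefix, remaining, slots):
        if slots == 1:
            yield prefix + [remaining]
            return
        for v in range(remaining + 1):
            yield from rec(prefix + [v], remaining - v, slots - 1)

    for point in rec([], k, n):
        yield [p / k for p in point]
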