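"""Independent reference implementations used to check the package.

These deliberately share no code with retrodup: a plain-Python affine
Smith-Waterman with traceback, an exact-rational Fisher enumeration, a
step-up BH reference, and a per-base interval intersection counter.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Dict, List, Tuple

NEG = float("-inf")


def sw_protein_dp(query: str, target: str, matrix,
                  gap_open: float = 11.0, gap_extend: float = 1.0
                  ) -> Tuple[float, float, int]:
    """Exhaustive affine local DP; returns (score, identity_pct,
    aligned_columns) of the best local alignment."""
    n, m = len(query), len(target)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    ptr: Dict[Tuple[int, int, int], Tuple[int, int, int]] = {}
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ix_from_m = M[i - 1][j] - gap_open
            ix_from_ix = Ix[i - 1][j] - gap_extend
            Ix[i][j] = max(ix_from_m, ix_from_ix)
            ptr[(1, i, j)] = ((0, i - 1, j) if ix_from_m >= ix_from_ix
                              else (1, i - 1, j))
            iy_from_m = M[i][j - 1] - gap_open
            iy_from_iy = Iy[i][j - 1] - gap_extend
            Iy[i][j] = max(iy_from_m, iy_from_iy)
            ptr[(2, i, j)] = ((0, i, j - 1) if iy_from_m >= iy_from_iy
                              else (2, i, j - 1))
            try:
                s = matrix[query[i - 1], target[j - 1]]
            except (KeyError, IndexError):
                s = -4.0
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            cand = diag + s
            if cand <= 0:
                M[i][j] = 0.0
                ptr[(0, i, j)] = None
            else:
                M[i][j] = cand
                src = (0 if diag == M[i - 1][j - 1]
                       else (1 if diag == Ix[i - 1][j - 1] else 2))
                ptr[(0, i, j)] = (src, i - 1, j - 1)
            if M[i][j] > best:
                best, best_pos = M[i][j], (0, i, j)
    if best_pos is None:
        return 0.0, 0.0, 0
    matches = cols = 0
    state = best_pos
    while state is not None:
        layer, i, j = state
        if layer == 0 and i > 0 and j > 0 and M[i][j] > 0:
            cols += 1
            if query[i - 1] == target[j - 1]:
                matches += 1
        nxt = ptr.get(state)
        if layer == 0 and (nxt is None or M[i][j] <= 0):
            break
        state = nxt
    return best, (100.0 * matches / cols if cols else 0.0), cols


def fisher_exact_fraction(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration in exact
    rational arithmetic (point-probability method)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)

    p_obs = pmf(a)
    return float(sum(p for x in range(lo, hi + 1)
                     if (p := pmf(x)) <= p_obs))


def bh_stepup(pvals: List[float], alpha: float = 0.05) -> List[float]:
    """Benjamini-Hochberg adjusted p-values, plain step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def overlap_bruteforce(a: Tuple[str, int, int],
                       b: Tuple[str, int, int]) -> int:
    """Per-base intersection count of two (chrom, start, end) intervals."""
    if a[0] != b[0]:
        return 0
    return sum(1 for pos in range(a[1], a[2]) if b[1] <= pos < b[2])
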