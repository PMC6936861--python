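"""Independent brute-force oracles used to validate the package's statistics.

Each function here is deliberately naive (enumeration, closed form, or
first-principles arithmetic) and shares no code with the implementation it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration (exact rationals).

    Fixes the margins of [[a, b], [c, d]] and sums P(k) over all k whose
    point probability does not exceed the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = probs[a]
    # tiny relative slack mirrors floating-point tie handling in practice
    return float(sum(p for p in probs.values() if p <= p_obs * Fraction(10**7 + 1, 10**7)))


def bh_step_up(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values from the textbook recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p_values[i] * m / rank)
        adjusted[i] = min(val, 1.0)
        prev = val
    return adjusted


def mann_whitney_exact_enumeration(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of group assignments.

    Assumes no ties. Returns (U for group a, p).
    """
    na = len(a)
    pooled = a + b
    order = sorted(pooled)
    rank = {v: i + 1 for i, v in enumerate(order)}

    def u_of(indices: tuple[int, ...]) -> float:
        r = sum(rank[pooled[i]] for i in indices)
        return r - na * (na + 1) / 2

    u_obs = u_of(tuple(range(na)))
    mean = na * len(b) / 2
    total = 0
    extreme = 0
    for idx in combinations(range(len(pooled)), na):
        total += 1
        if abs(u_of(idx) - mean) >= abs(u_obs - mean) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def enumerate_free_end_gap_alignments(
    seq_a: str,
    seq_b: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best score over every global alignment, scoring end gap runs as zero.

    A gap run's cost is open + extend*(len-1) unless the run touches either
    end of the alignment in its own sequence, in which case it is free.
    Intended for tiny sequences (<= ~6 nt); purely recursive enumeration.
    """

    def score(ga: str, gb: str) -> float:
        total = 0.0
        for gapped in (ga, gb):
            i = 0
            while i < len(gapped):
                if gapped[i] == "-":
                    j = i
                    while j < len(gapped) and gapped[j] == "-":
                        j += 1
                    if i != 0 and j != len(gapped):
                        total += gap_open + gap_extend * (j - i - 1)
                    i = j
                else:
                    i += 1
        for x, y in zip(ga, gb):
            if x != "-" and y != "-":
                total += match if x == y else mismatch
        return total

    best = float("-inf")

    def rec(i: int, j: int, ga: str, gb: str) -> None:
        nonlocal best
        if i == len(seq_a) and j == len(seq_b):
            best = max(best, score(ga, gb))
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, ga + seq_a[i], gb + seq_b[j])
        if i < len(seq_a):
            rec(i + 1, j, ga + seq_a[i], gb + "-")
        if j < len(seq_b):
            rec(i, j + 1, ga + "-", gb + seq_b[j])

    rec(0, 0, "", "")
    return best


def pearson_closed_form(x: list[float], y: list[float]) -> float:
    """Sample correlation straight from the definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    return sxy / (sxx * syy) ** 0.5
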