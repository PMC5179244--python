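"""Independent brute-force oracles for the overlap statistic.

Everything here recomputes quantities from first principles — exhaustive
enumeration of subset placements, exact rational arithmetic on binomial
coefficients, or Monte Carlo placement — and deliberately shares no code
with :mod:`nbarscan.score`. Used by the test suite to validate the fast
implementation; far too slow for production sweeps.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np

__all__ = [
    "enumerate_expected_shared",
    "oracle_expected_shared",
    "brute_force_expected_shared",
    "oracle_pair_score",
    "oracle_matrix_scores",
]


def enumerate_expected_shared(n: int, d_i: int, d_j: int) -> float:
    """Exact expectation of |A ∩ B| over ALL placements of the two subsets.

    Enumerates every pair of subsets A, B of {1..n} with |A| = d_i,
    |B| = d_j. Exponential cost; keep n small (<= ~12).
    """
    total = Fraction(0)
    count = 0
    sets_j = [frozenset(c) for c in combinations(range(n), d_j)]
    for a in combinations(range(n), d_i):
        sa = frozenset(a)
        for sb in sets_j:
            total += len(sa & sb)
            count += 1
    return float(Fraction(total, count))


def oracle_expected_shared(n: int, d_i: int, d_j: int) -> float:
    """Exact expectation via direct binomial-coefficient summation.

    sum_k k * C(d_j, k) C(n - d_j, d_i - k) / C(n, d_i), in exact rational
    arithmetic with ``math.comb``.
    """
    total = Fraction(0)
    denom = comb(n, d_i)
    for k in range(max(0, d_i + d_j - n), min(d_i, d_j) + 1):
        total += Fraction(k * comb(d_j, k) * comb(n - d_j, d_i - k), denom)
    return float(total)


def brute_force_expected_shared(
    n: int, d_i: int, d_j: int, n_draws: int, seed: int
) -> float:
    """Monte-Carlo mean shared count over independent uniform placements.

    Each draw places d_i and d_j neighbors independently and uniformly at
    random among n slots and counts the overlap; reproducible given seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not (1 <= d_i <= n and 1 <= d_j <= n):
        raise ValueError("degrees must satisfy 1 <= d <= n")
    rng = np.random.default_rng(seed)
    total = 0
    done = 0
    while done < n_draws:
        m = min(n_draws - done, 200_000)
        # rank-threshold of iid uniforms = uniformly random d-subset per row
        a = rng.random((m, n)).argsort(axis=1) < d_i
        b = rng.random((m, n)).argsort(axis=1) < d_j
        total += int((a & b).sum())
        done += m
    return total / n_draws


def oracle_pair_score(S: int, n: int, d_i: int, d_j: int) -> Optional[float]:
    """From-scratch pair score in exact arithmetic; None for degenerate pairs."""
    smin = max(0, d_i + d_j - n)
    smax = min(d_i, d_j)
    if not smin <= S <= smax:
        raise ValueError(f"infeasible S={S} for n={n}, d_i={d_i}, d_j={d_j}")
    if smin == smax:
        return None
    p = Fraction(0)
    denom = comb(n, d_i)
    for k in range(smin, smax + 1):
        p += Fraction(k * comb(d_j, k) * comb(n - d_j, d_i - k), denom)
    dev = Fraction(S) - p
    if dev > 0:
        return float(dev / (Fraction(smax) - p))
    if dev < 0:
        return float(dev / (p - Fraction(smin)))
    return 0.0


def oracle_matrix_scores(entries, axis: str) -> list:
    """All pair scores on one axis by plain Python loops (None = degenerate)."""
    rows = [list(r) for r in entries] if axis == "rows" else [
        list(c) for c in zip(*entries)
    ]
    n = len(rows[0])
    out = []
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            s = sum(1 for x, y in zip(rows[a], rows[b]) if x and y)
            d_a = sum(rows[a])
            d_b = sum(rows[b])
            out.append(oracle_pair_score(s, n, d_a, d_b))
    return out
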