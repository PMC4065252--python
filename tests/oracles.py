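"""Independent brute-force oracles used to verify the statistical kernels.

Everything here is deliberately naive: exact rational arithmetic and full
enumeration, sharing no code path with the package implementations.
"""

from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import comb


@lru_cache(maxsize=None)
def _hypergeom_pmf_exact(m1: int, n: int, h: int) -> tuple[tuple[int, Fraction], ...]:
    """Exact point masses of the top-left cell over its support.

    Margins: rows (m1, n - m1), columns (h, n - h).
    """
    a_min = max(0, h - (n - m1))
    a_max = min(m1, h)
    denom = comb(n, h)
    return tuple(
        (a, Fraction(comb(m1, a) * comb(n - m1, h - a), denom))
        for a in range(a_min, a_max + 1)
    )


@lru_cache(maxsize=None)
def fisher_two_sided_exact_by_a(m1: int, n: int, h: int) -> tuple[tuple[int, Fraction], ...]:
    """Exact two-sided Fisher P for every achievable top-left cell.

    All point masses share the denominator C(n, h), so the "as or less
    probable" comparison reduces to exact integer comparison of numerators.
    """
    a_min = max(0, h - (n - m1))
    a_max = min(m1, h)
    denom = comb(n, h)
    nums = {a: comb(m1, a) * comb(n - m1, h - a) for a in range(a_min, a_max + 1)}
    return tuple(
        (a, Fraction(sum(v for v in nums.values() if v <= nums[a]), denom))
        for a in nums
    )


def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher exact P by enumeration of all tables with the
    observed margins, in exact rational arithmetic."""
    (a, b), (c, d) = table
    return dict(fisher_two_sided_exact_by_a(a + b, a + b + c + d, a + c))[a]


def mann_whitney_two_sided_exact(x, y) -> Fraction:
    """Exact two-sided Mann-Whitney P by enumeration of all group
    assignments of the pooled (tie-free) values."""
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free values"
    n1 = len(x)

    def u_min(group1):
        group2 = [v for v in pooled if v not in group1]
        u1 = sum(1 for a in group1 for b in group2 if a > b)
        return min(u1, n1 * (len(pooled) - n1) - u1)

    observed = u_min(x)
    total = comb(len(pooled), n1)
    extreme = sum(
        1 for g1 in combinations(pooled, n1) if u_min(list(g1)) <= observed
    )
    return Fraction(extreme, total)


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact summation."""
    denom = comb(N, n)
    top = min(K, n)
    return sum(
        Fraction(comb(K, j) * comb(N - K, n - j), denom) for j in range(k, top + 1)
    )
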