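"""Independent brute-force oracles used to check the implementation.

Each oracle is deliberately written in the most direct style possible
(explicit enumeration, exact rational arithmetic, plain loops) and shares no
code with the package.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

from scipy import stats

#: relative tolerance for point-probability ties in the two-sided rule
TIE_TOL = Fraction(10**7 + 1, 10**7)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided Fisher p by exhaustive table enumeration.

    Enumerates every 2x2 table with the observed margins, computes exact
    rational hypergeometric point probabilities, and sums those not
    exceeding the observed probability (with a 1e-7 relative tie
    tolerance).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p_x <= p_obs * TIE_TOL:
            total += p_x
    return float(min(total, Fraction(1)))


def logrank_sum(times_a, times_b):
    """Two-sample log-rank by direct per-event-time summation.

    Uncensored death times only. Returns (U, V, chi2, p).
    """
    pooled = sorted(set(list(times_a) + list(times_b)))
    u = 0.0
    v = 0.0
    for t in pooled:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        n = n_a + n_b
        d_a = sum(1 for x in times_a if x == t)
        d_b = sum(1 for x in times_b if x == t)
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        u += d_a - d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2 = u * u / v if v > 0 else float("nan")
    p = float(stats.chi2.sf(chi2, 1)) if v > 0 else 1.0
    return u, v, chi2, p


def overlap_upper_tail(n_universe: int, size_a: int, size_b: int, k: int) -> float:
    """P(|A' ∩ B| >= k) by enumerating all C(N, |A|) draws of A'.

    B is fixed as the first ``size_b`` elements of the universe; by symmetry
    the distribution of the intersection size depends only on the sizes.
    Exact rational arithmetic; feasible for N <= 15.
    """
    b_set = set(range(size_b))
    hits = sum(
        1
        for a_draw in combinations(range(n_universe), size_a)
        if len(b_set.intersection(a_draw)) >= k
    )
    return float(Fraction(hits, comb(n_universe, size_a)))
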