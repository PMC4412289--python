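"""Independent brute-force oracles used only by the test suite.

All enumeration is done in exact rational arithmetic (fractions.Fraction)
so the oracles share no code path — and no floating-point pmf — with the
implementations they check.  The minimum-likelihood tie tolerance (relative
1e-7) mirrors the implementation's documented convention.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

TIE_TOL = Fraction(10000001, 10000000)  # 1 + 1e-7


def binomial_two_sided_oracle(k: int, n: int, p0: Fraction | float) -> float:
    """Full enumeration of the two-sided binomial p-value."""
    p0 = Fraction(p0)
    q0 = 1 - p0
    pmf = [comb(n, i) * p0**i * q0 ** (n - i) for i in range(n + 1)]
    cutoff = pmf[k] * TIE_TOL
    return float(sum(x for x in pmf if x <= cutoff))


def fisher_two_sided_oracle(table) -> float:
    """Hypergeometric enumeration over all tables with the fixed margins."""
    (a, b), (c, d) = table
    r1, c1, c2 = a + b, a + c, b + d
    n = a + b + c + d
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    denom = comb(n, r1)
    pmf = {
        k: Fraction(comb(c1, k) * comb(c2, r1 - k), denom) for k in range(lo, hi + 1)
    }
    cutoff = pmf[a] * TIE_TOL
    return float(sum(x for x in pmf.values() if x <= cutoff))


def bh_oracle(pvals):
    """Literal step-up definition: q_i = min over j with p_(j) >= p_(i) of
    p_(j) * m / rank_j (independent of the vectorized implementation)."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    qs = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        best = min(best, pvals[i] * m / rank)
        qs[i] = best
    return qs


def spearman_exact_permutation_p(x, y) -> float:
    """Exact permutation p-value for |rho| >= |observed| (small n only)."""
    from itertools import permutations

    import numpy as np
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)

    def rho(a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))

    observed = abs(rho(rx, ry))
    count = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(rho(rx, perm)) >= observed - 1e-12:
            count += 1
    return count / total
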