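"""Exact statistical primitives shared by every analysis stage.

All count-based tests here are *exact* (enumeration-defined) rather than
asymptotic, because allelic and pooled read counts can be small and the
downstream classification applies very stringent FDR thresholds where tail
accuracy matters.  Two-sided p-values for the binomial and Fisher tests use
the minimum-likelihood definition: the sum of point probabilities of all
outcomes no more probable than the observed one.  Ties in point
probabilities are resolved with a relative tolerance of 1e-7, matching the
convention of mainstream statistical software.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "UndefinedTestError",
    "DegenerateTableError",
    "binomial_exact_two_sided",
    "fisher_exact_two_sided",
    "chi2_heterogeneity",
    "bh_fdr",
    "spearman_correlation",
    "one_way_anova",
]

#: relative tolerance used when comparing point probabilities for the
#: minimum-likelihood two-sided definition
REL_TIE_TOL = 1 + 1e-7


class UndefinedTestError(ValueError):
    """The requested test is undefined for the given input (e.g. no trials)."""


class DegenerateTableError(ValueError):
    """A contingency table has an expected cell of zero."""


def binomial_exact_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial test of ``k`` successes in ``n`` trials.

    The p-value sums Binomial(n, p0) point probabilities over all outcomes
    whose probability is at most that of ``k`` (method of small p-values).

    Parameters
    ----------
    k : observed number of successes, ``0 <= k <= n``.
    n : number of trials, ``n >= 1``.
    p0 : null success probability, strictly inside (0, 1).
    """
    k = int(k)
    n = int(n)
    if n < 1:
        raise UndefinedTestError("binomial test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} must be in (0, 1)")

    def pmf(i: int) -> float:
        return float(sps.binom.pmf(i, n, p0))

    cutoff = pmf(k) * REL_TIE_TOL
    mode = min(int(np.floor((n + 1) * p0)), n)
    if pmf(mode) <= cutoff:
        return 1.0
    if k < mode:
        # left tail observed; binary-search the smallest j > mode whose point
        # probability drops to or below the cutoff (pmf decreases past mode)
        p = float(sps.binom.cdf(k, n, p0))
        if pmf(n) <= cutoff:
            lo, hi = mode + 1, n
            while lo < hi:
                mid = (lo + hi) // 2
                if pmf(mid) <= cutoff:
                    hi = mid
                else:
                    lo = mid + 1
            p += float(sps.binom.sf(lo - 1, n, p0))
    else:
        # right tail observed; find the largest j < mode at or below cutoff
        p = float(sps.binom.sf(k - 1, n, p0))
        if pmf(0) <= cutoff:
            lo, hi = 0, mode - 1
            while lo < hi:
                mid = (lo + hi + 1) // 2
                if pmf(mid) <= cutoff:
                    lo = mid
                else:
                    hi = mid - 1
            p += float(sps.binom.cdf(lo, n, p0))
    return float(min(1.0, max(p, 5e-324)))


def fisher_exact_two_sided(table: Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    With all margins fixed, sums hypergeometric probabilities of all tables
    no more probable than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    total = a + b + c + d
    if total == 0:
        raise UndefinedTestError("Fisher test undefined for an empty table")
    r1 = a + b
    c1 = a + c
    c2 = b + d
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)

    def log_binom(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    logpmf = (
        log_binom(c1, support)
        + log_binom(c2, r1 - support)
        - log_binom(total, r1)
    )
    logpmf -= np.log(np.exp(logpmf - logpmf.max()).sum()) + logpmf.max()
    cutoff = logpmf[a - lo] + np.log(REL_TIE_TOL)
    p = float(np.exp(logpmf[logpmf <= cutoff]).sum())
    return float(min(1.0, max(p, 5e-324)))


def chi2_heterogeneity(counts: Sequence[Sequence[int]] | np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared test of homogeneous allelic proportion across rows.

    ``counts`` is a K x 2 table (maternal, paternal counts per cross); the
    null is that the column proportion is identical in every row.  The
    statistic is Pearson's without continuity correction, df = K - 1.

    Returns (statistic, p-value).
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError(f"expected a K x 2 table, got shape {t.shape}")
    k = t.shape[0]
    if k < 2:
        raise ValueError("need at least two rows")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row <= 0).any():
        raise ValueError("every row total must be positive")
    n = t.sum()
    expected = np.outer(row, col) / n
    if (expected == 0).any():
        raise DegenerateTableError("expected cell count of zero (empty column)")
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=k - 1))
    return stat, p


def bh_fdr(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min_{j : p_(j) >= p_(i)} p_(j) * m / rank(j), capped at 1.  An
    empty input returns an empty array.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    m = p.size
    if m == 0:
        return np.array([], dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The p-value comes from the large-sample t approximation.  Requires at
    least four paired observations and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if abs(rho) >= 1.0:
        # perfect monotone association: below the resolution of the t
        # approximation
        return (1.0 if rho > 0 else -1.0), 0.0
    return rho, float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects F test across replicate groups.

    Returns ``(F, p)``.  When the within-group variance is exactly zero but
    groups differ, returns ``(inf, 0.0)`` as a "below machine floor"
    sentinel instead of dividing by zero.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one value")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_between = k - 1
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("total within-group degrees of freedom must be >= 1")
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def nb_exact_test(s_a: int, s_b: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Exact two-group negative-binomial test on pooled pseudo-counts.

    Conditions on the total ``s_a + s_b``: with a common dispersion phi the
    group sums are NB with sizes ``n_a/phi`` and ``n_b/phi`` and a shared
    success probability, so the conditional law of ``s_b`` given the total is
    free of the mean.  The two-sided p-value is minimum-likelihood over that
    conditional distribution.  ``dispersion = 0`` degenerates to a binomial
    split proportional to group sizes.
    """
    s_a, s_b = int(s_a), int(s_b)
    if min(s_a, s_b) < 0 or min(n_a, n_b) < 1:
        raise ValueError("counts must be non-negative and group sizes >= 1")
    total = s_a + s_b
    if total == 0:
        raise UndefinedTestError("no reads in either group")
    if dispersion <= 1e-12:
        return binomial_exact_two_sided(s_b, total, n_b / (n_a + n_b))
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    s = np.arange(total + 1)
    logw = (
        gammaln(s + r_b)
        - gammaln(s + 1)
        + gammaln(total - s + r_a)
        - gammaln(total - s + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    p = float(w[w <= w[s_b] * REL_TIE_TOL].sum())
    return float(min(1.0, max(p, 5e-324)))
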