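"""Significance tests used throughout the figure-style outputs.

Three procedures with a uniform contract: Mann-Whitney U (exact for small
samples, normal approximation with tie correction otherwise), Welch's
unpaired t-test with Satterthwaite degrees of freedom, and one-way ANOVA.
On two groups the ANOVA F equals the squared pooled-variance t statistic.

The exact Mann-Whitney branch enumerates the null distribution of U by the
classic dynamic-programming recurrence (count of rank subsets per U value),
used whenever both samples have at most 20 observations and there are no
ties; it matches brute-force enumeration of all C(n1+n2, n1) rank
assignments.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg helper is provided for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "t_test_unequal_var",
    "one_way_anova",
    "benjamini_hochberg",
    "EXACT_MAX_N",
]

#: per-group sample size at or below which the exact U distribution is used
EXACT_MAX_N = 20

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: tuple = ()
    method: str = ""
    n: tuple = ()

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": list(self.df),
            "method": self.method,
            "n": list(self.n),
        }


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple:
    """Counts c[u] of rank subsets of size n1 from n1+n2 with U statistic u.

    Recurrence: c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u), i.e. the
    largest rank goes to group 1 (adding n2 to U) or to group 2.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_null_counts(n1 - 1, n2)  # shifted by n2
    b = _u_null_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _exact_u_p_two_sided(u: float, n1: int, n2: int) -> float:
    """Two-sided p = 2 * P(U <= min(u, n1*n2 - u)) under the exact null."""
    counts = np.asarray(_u_null_counts(n1, n2), dtype=float)
    total = counts.sum()
    u_small = min(u, n1 * n2 - u)
    p = 2.0 * counts[: int(np.floor(u_small)) + 1].sum() / total
    return min(1.0, p)


def mann_whitney_u(a, b) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Reports U for the first sample (U1 = R1 - n1(n1+1)/2).  With both group
    sizes <= 20 and no ties the exact enumeration is used; otherwise the
    normal approximation with tie correction and continuity correction.
    Identical pooled values yield p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if np.all(pooled == pooled[0]):
        return TestResult("mann_whitney_u", float(u1), 1.0, method="degenerate", n=(n1, n2))

    if not has_ties and max(n1, n2) <= EXACT_MAX_N:
        p = _exact_u_p_two_sided(u1, n1, n2)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        if sigma == 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / sigma  # continuity-corrected
            p = 2.0 * sps.norm.sf(max(z, 0.0))
        p = min(1.0, p)
        method = "normal_approx"
    return TestResult("mann_whitney_u", float(u1), float(p), method=method, n=(n1, n2))


def t_test_unequal_var(a, b) -> TestResult:
    """Unpaired two-tailed Student's t-test with unequal variance (Welch).

    Degenerate inputs: zero variance in both groups gives p = 1 for equal
    means; for unequal means p is floored at machine tiny rather than 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, 1.0, df=(a.size + b.size - 2,),
                              method="degenerate", n=(a.size, b.size))
        return TestResult("welch_t", float("inf"), _P_FLOOR,
                          df=(a.size + b.size - 2,), method="degenerate",
                          n=(a.size, b.size))
    res = sps.ttest_ind(a, b, equal_var=False)
    p = max(float(res.pvalue), _P_FLOOR)
    return TestResult("welch_t", float(res.statistic), p, df=(float(res.df),),
                      method="welch_satterthwaite", n=(a.size, b.size))


def one_way_anova(*groups) -> TestResult:
    """One-way ANOVA across two or more groups.

    On two groups F equals the square of the pooled-variance t statistic.
    All values identical gives F = 0, p = 1; zero within-group variance with
    distinct means gives an infinite F with p floored at machine tiny.
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        try:
            groups = tuple(np.asarray(g, dtype=float) for g in groups[0])
        except (TypeError, ValueError):
            pass
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least two values for ANOVA")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    dfb, dfw = k - 1, n_total - k
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("one_way_anova", 0.0, 1.0, df=(dfb, dfw),
                          method="degenerate", n=tuple(g.size for g in groups))
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if within == 0:
        return TestResult("one_way_anova", float("inf"), _P_FLOOR, df=(dfb, dfw),
                          method="degenerate", n=tuple(g.size for g in groups))
    f, p = sps.f_oneway(*groups)
    return TestResult("one_way_anova", float(f), float(max(p, _P_FLOOR)),
                      df=(dfb, dfw), method="fisher", n=tuple(g.size for g in groups))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (off by default everywhere; provided for completeness)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
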