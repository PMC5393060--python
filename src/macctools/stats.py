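"""Rank-based two-group and paired tests.

Implemented from first principles (exact small-sample null distributions via
dynamic programming, normal approximation with tie correction otherwise) so
they can be validated against external reference implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RankTestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
]

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    method: str  # "exact" or "asymptotic"


def _tie_counts(ranks: np.ndarray) -> np.ndarray:
    _, counts = np.unique(ranks, return_counts=True)
    return counts


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_exact_sf(n1: int, n2: int) -> np.ndarray:
    """Survival function P(U >= u) of the null U distribution (no ties).

    Counts arrangements by dynamic programming over the merged ranking:
    placing the k-th first-sample observation at overall rank t contributes
    t - k second-sample observations lying below it.
    """
    u_max = n1 * n2
    dp = np.zeros((n1 + 1, u_max + 1))
    dp[0, 0] = 1.0
    for t in range(1, n1 + n2 + 1):
        new = dp.copy()  # slot t taken by a second-sample value
        for k in range(1, min(t, n1) + 1):
            gain = t - k
            if gain == 0:
                new[k, :] += dp[k - 1, :]
            else:
                new[k, gain:] += dp[k - 1, :-gain]
        # forbid more than n2 second-sample values among first t slots
        for k in range(n1 + 1):
            if t - k > n2:
                new[k, :] = 0.0
        dp = new
    counts = dp[n1]
    total = counts.sum()
    pmf = counts / total
    return np.cumsum(pmf[::-1])[::-1]  # sf[u] = P(U >= u)


def mann_whitney(x, y, alternative: str = "two-sided",
                 method: str = "auto", use_continuity: bool = True) -> RankTestResult:
    """Mann-Whitney U rank-sum test.

    ``method='auto'`` uses the exact null distribution when both samples have
    at most 8 observations and there are no ties, otherwise the normal
    approximation with tie correction (and continuity correction).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")

    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    ties = _tie_counts(combined)
    has_ties = np.any(ties > 1)

    if np.all(combined == combined[0]):
        warnings.warn("all values tied; Mann-Whitney p set to 1")
        return RankTestResult(statistic=u1, pvalue=1.0, method="degenerate")

    if method == "auto":
        method = "exact" if (not has_ties and max(n1, n2) <= 8) else "asymptotic"
    if method == "exact" and has_ties:
        raise ValueError("exact method is not defined with ties")

    if method == "exact":
        sf = _mwu_exact_sf(n1, n2)
        p_greater = float(sf[int(round(u1))])
        p_less = float(sf[int(round(u2))])
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(2.0 * min(p_greater, p_less), 1.0)
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = ((ties ** 3 - ties).sum()) / (n * (n - 1)) if n > 1 else 0.0
        sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        cc = 0.5 if use_continuity else 0.0

        def one_sided(u):
            return float(norm.sf((u - mu - cc) / sigma))

        if alternative == "greater":
            p = one_sided(u1)
        elif alternative == "less":
            p = one_sided(u2)
        else:
            p = min(2.0 * one_sided(max(u1, u2)), 1.0)

    return RankTestResult(statistic=float(u1), pvalue=float(p), method=method)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _wsr_exact_sf(ranks: np.ndarray) -> np.ndarray:
    """Survival function of W+ under random sign flips for given |d| ranks.

    Works with midranks from ties: ranks are doubled to integers and the
    returned array is indexed by the DOUBLED statistic.
    """
    r2 = np.rint(2 * np.asarray(ranks)).astype(int)
    counts = np.zeros(r2.sum() + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r].copy()
    pmf = counts / counts.sum()
    return np.cumsum(pmf[::-1])[::-1]


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided",
                         method: str = "auto", correction: bool = False) -> RankTestResult:
    """Wilcoxon signed-rank test on paired differences (or one sample).

    Zero differences are dropped (Wilcoxon convention). ``alternative='greater'``
    tests whether x - y is shifted positive. Statistic is W+ (rank sum of
    positive differences).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; signed-rank p set to 1")
        return RankTestResult(statistic=0.0, pvalue=1.0, method="degenerate")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    ties = _tie_counts(np.abs(d))
    has_ties = np.any(ties > 1)

    if method == "auto":
        method = "exact" if n <= 25 else "asymptotic"

    if method == "exact":
        sf = _wsr_exact_sf(ranks)
        p_greater = float(sf[int(round(2 * w_plus))])
        p_less = float(sf[int(round(2 * w_minus))])
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(2.0 * min(p_greater, p_less), 1.0)
    else:
        mu = n * (n + 1) / 4.0
        tie_term = (ties ** 3 - ties).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = w_plus - mu
        if correction:
            z -= np.sign(z) * 0.5
        z /= sigma
        if alternative == "greater":
            p = float(norm.sf(z))
        elif alternative == "less":
            p = float(norm.cdf(z))
        else:
            p = min(2.0 * float(norm.sf(abs(z))), 1.0)

    return RankTestResult(statistic=w_plus, pvalue=float(p), method=method)
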