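"""Shared nonparametric statistics helpers.

Hodges–Lehmann location estimates and exact confidence intervals for the
one-sample signed-rank and two-sample rank-sum settings. scipy provides the
test statistics and p-values but not these estimators, so they live here.
Exact null distributions are computed by dynamic programming (no ties
assumed, the standard convention); large samples fall back to the normal
approximation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# Above these sizes the exact DP tables get large and the normal
# approximation is accurate to well under half a rank.
_EXACT_SIGNED_RANK_MAX_N = 40
_EXACT_RANK_SUM_MAX_MN = 1600


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (e.g. all-zero differences)."""


def walsh_averages(d: np.ndarray) -> np.ndarray:
    """All pairwise averages (d_i + d_j)/2 for i <= j, sorted."""
    d = np.asarray(d, dtype=float)
    n = d.size
    i, j = np.triu_indices(n)
    return np.sort((d[i] + d[j]) / 2.0)


def hodges_lehmann_one_sample(d) -> float:
    """Pseudo-median: median of the Walsh averages of paired differences."""
    return float(np.median(walsh_averages(np.asarray(d, dtype=float))))


def signed_rank_counts(n: int) -> np.ndarray:
    """Number of rank subsets of {1..n} summing to each value 0..n(n+1)/2."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: total + 1 - r].copy()
    return counts


def signed_rank_ci(d, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (or normal-approximate) CI for the one-sample pseudo-median.

    The bounds are order statistics of the Walsh averages with index set by
    the signed-rank null distribution.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    w = walsh_averages(d)
    m = w.size
    if n <= _EXACT_SIGNED_RANK_MAX_N:
        counts = signed_rank_counts(n)
        cdf = np.cumsum(counts) / counts.sum()
        # largest k with P(W <= k-1) <= alpha/2; k in Walsh-average units
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right"))
    else:
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(np.floor(mu + stats.norm.ppf(alpha / 2.0) * sigma))
    k = max(0, min(k, (m - 1) // 2))
    return float(w[k]), float(w[m - 1 - k])


def hodges_lehmann_two_sample(x, y) -> float:
    """Median of all pairwise differences x_i - y_j (shift of x relative to y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.median(np.subtract.outer(x, y)))


def rank_sum_counts(m: int, n: int) -> np.ndarray:
    """Null distribution counts of the Mann–Whitney U statistic over 0..m*n.

    Uses the recursion c_{m,n}(u) = c_{m-1,n}(u-n) + c_{m,n-1}(u): the largest
    pooled observation is either an x (contributing n to U) or a y.
    """
    size = m * n + 1
    table = np.zeros((m + 1, size))
    table[:, 0] = 1.0  # zero y's: U is necessarily 0
    for nn in range(1, n + 1):
        new = np.zeros_like(table)
        new[0, 0] = 1.0
        for mm in range(1, m + 1):
            shifted = np.zeros(size)
            shifted[nn:] = new[mm - 1, : size - nn]
            new[mm] = shifted + table[mm]
        table = new
    return table[m]


def rank_sum_ci(x, y, alpha: float = 0.05) -> tuple[float, float]:
    """CI for the two-sample location shift (x relative to y), HL-based."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    total = m * n
    if total <= _EXACT_RANK_SUM_MAX_MN:
        counts = rank_sum_counts(m, n)
        cdf = np.cumsum(counts) / counts.sum()
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right"))
    else:
        mu = total / 2.0
        sigma = np.sqrt(m * n * (m + n + 1) / 12.0)
        k = int(np.floor(mu + stats.norm.ppf(alpha / 2.0) * sigma))
    k = max(0, min(k, (total - 1) // 2))
    return float(diffs[k]), float(diffs[total - 1 - k])


def signed_rank_test(d, alpha: float = 0.05):
    """Wilcoxon signed-rank V, HL estimate, CI and two-sided p for differences d."""
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    res = stats.wilcoxon(d, alternative="two-sided", zero_method="wilcox",
                         method="auto")
    est = hodges_lehmann_one_sample(d)
    lo, hi = signed_rank_ci(d, alpha)
    return float(res.statistic), est, (lo, hi), float(res.pvalue)


def rank_sum_test(x, y, alpha: float = 0.05):
    """Two-sided Wilcoxon rank-sum with HL shift estimate and CI (x minus y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    est = hodges_lehmann_two_sample(x, y)
    lo, hi = rank_sum_ci(x, y, alpha)
    return float(res.statistic), est, (lo, hi), float(res.pvalue)
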