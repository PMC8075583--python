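"""Rank-based statistics shared by the pause and gene-set layers.

The two-sided Wilcoxon rank-sum test is computed exactly (permutation of
midranks, dynamic programming over subset rank-sums) when both groups
have at most ``EXACT_MAX`` observations, and by the normal approximation
with midranks and tie-corrected variance otherwise.  No continuity
correction is applied on the asymptotic branch.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import stats as sps

EXACT_MAX = 8


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of two samples.

    Returns ``(W, p)`` where W is the rank sum of the first sample in the
    pooled midranking.  Exact when ``len(a) <= 8`` and ``len(b) <= 8``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    n, m = a.size, b.size
    ranks = _midranks(np.concatenate([a, b]))
    w = float(ranks[:n].sum())
    if n <= EXACT_MAX and m <= EXACT_MAX:
        return w, _exact_p(ranks, n, w)
    return w, _asymptotic_p(ranks, n, m, w)


def _exact_p(ranks: np.ndarray, n: int, w_obs: float) -> float:
    """Exact two-sided p by DP over all C(N, n) rank subsets.

    Midranks are multiples of 1/2, so doubling gives integers and the
    whole computation stays exact; deviations from the null mean are
    compared after a further multiplication by N to clear the division.
    """
    scaled = [int(round(2 * r)) for r in ranks]
    total = sum(scaled)
    big = len(scaled)
    # dp[k] = Counter of achievable scaled rank-sums using subsets of size k
    dp: list[Counter] = [Counter() for _ in range(n + 1)]
    dp[0][0] = 1
    for r in scaled:
        for k in range(min(n, big) - 1, -1, -1):
            if not dp[k]:
                continue
            tgt = dp[k + 1]
            for s, c in dp[k].items():
                tgt[s + r] += c
    dist = dp[n]
    n_subsets = sum(dist.values())
    # |W*N - n*total/ (2)| comparison, all integers: dev = |2*W*N - n*total|
    dev_obs = abs(int(round(2 * w_obs)) * big - n * total)
    hits = sum(c for s, c in dist.items() if abs(s * big - n * total) >= dev_obs)
    return hits / n_subsets


def _asymptotic_p(ranks: np.ndarray, n: int, m: int, w: float) -> float:
    big = n + m
    mu = n * (big + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((big + 1) - tie_term / (big * (big - 1)))
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def two_sample_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test with degenerate-input guards.

    Identical constant groups give ``(0, 1)``; distinct constant groups
    give ``(inf, 0)`` with the sign of the mean difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t requires >= 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        diff = a.mean() - b.mean()
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pearson_r(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("pearson_r requires two equal-length samples, n >= 3")
    return float(sps.pearsonr(a, b).statistic)
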