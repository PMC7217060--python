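"""Shared statistical primitives: Fisher tests and the rank-sum test.

The 2x2 Fisher test delegates to scipy; the 2xk generalisation uses a
seeded Monte-Carlo version of Fisher's probability ordering (tables drawn
from the fixed-margin multivariate hypergeometric null).  The rank-sum
(Mann-Whitney) test is exact where feasible and falls back to the normal
approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = ["fisher_exact_2x2", "mc_fisher_2xk", "rank_sum_test"]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError(f"need a non-negative 2x2 table, got {table!r}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate margin in 2x2 table %s; p = 1", table.tolist())
        return 1.0
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def _log_table_prob(row1: np.ndarray, col_totals: np.ndarray, n1: int, n: int) -> np.ndarray:
    """log P(row1 | margins) under the fixed-margin null (vectorised over rows)."""
    row1 = np.atleast_2d(row1)
    row2 = col_totals[None, :] - row1
    lp = (
        gammaln(n1 + 1)
        + gammaln(n - n1 + 1)
        - gammaln(n + 1)
        + np.sum(gammaln(col_totals + 1))
        - np.sum(gammaln(row1 + 1), axis=1)
        - np.sum(gammaln(row2 + 1), axis=1)
    )
    return lp


def mc_fisher_2xk(
    table, n_permutations: int = 100_000, seed: int | None = 0
) -> float:
    """Seeded Monte-Carlo Fisher test for a 2xk table (two-sided).

    The statistic is the null probability of the table given its margins;
    p is the add-one-smoothed fraction of sampled tables at most as
    probable as the observed one (Fisher's probability ordering).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2 or (table < 0).any():
        raise ValueError("need a non-negative 2xk table")
    col_totals = table.sum(axis=0)
    keep = col_totals > 0
    table, col_totals = table[:, keep], col_totals[keep]
    if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
        return 1.0
    n1 = int(table[0].sum())
    n = int(table.sum())
    rng = np.random.default_rng(seed)
    obs_lp = _log_table_prob(table[0], col_totals, n1, n)[0]
    sampled = rng.multivariate_hypergeometric(col_totals, n1, size=n_permutations)
    lp = _log_table_prob(sampled, col_totals, n1, n)
    hits = int(np.sum(lp <= obs_lp + 1e-9))
    return (1 + hits) / (1 + n_permutations)


def _rank_sum_statistic(x: np.ndarray, pooled_ranks: np.ndarray, n1: int) -> float:
    return float(pooled_ranks[:n1].sum())


def rank_sum_test(
    x, y, exact_max_combinations: int = 200_000
) -> dict:
    """Two-sided rank-sum (Mann-Whitney) test with mid-ranks for ties.

    Without ties the exact null distribution is used whenever the combined
    sample size is at most 30.  With ties the exact conditional null is
    enumerated when the number of group assignments is small enough;
    otherwise the normal approximation with tie and continuity corrections
    applies.  Returns statistic U (for x), p, medians and the method used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    n_comb = _comb(n1 + n2, n1)

    if not has_ties and (n1 + n2 <= 30 or max(n1, n2) <= 25):
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        u = float(res.statistic)
    elif has_ties and n_comb <= exact_max_combinations:
        method = "exact_permutation"
        u, p = _exact_permutation(pooled, n1)
    else:
        method = "normal_approximation"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        u = float(res.statistic)
    return {
        "U": u,
        "p": min(p, 1.0),
        "median_x": float(np.median(x)),
        "median_y": float(np.median(y)),
        "method": method,
    }


def _comb(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _exact_permutation(pooled: np.ndarray, n1: int) -> tuple[float, float]:
    """Full enumeration of the conditional rank-sum null (mid-ranks)."""
    n = pooled.size
    ranks = sps.rankdata(pooled)
    obs = float(ranks[:n1].sum())
    mean = n1 * (n + 1) / 2.0
    obs_dev = abs(obs - mean)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        s = float(ranks[list(idx)].sum())
        total += 1
        if abs(s - mean) >= obs_dev - 1e-9:
            count += 1
    u = obs - n1 * (n1 + 1) / 2.0
    return u, count / total
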