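"""Spearman rank correlation with exact small-sample significance.

For n untied observations Spearman's rho is

    rho = 1 - 6 * S / (n * (n^2 - 1)),    S = sum_i d_i^2,

with d_i the rank differences.  Under the null all n! rank permutations are
equally likely, so the exact distribution of rho follows from counting
permutations by their value of S.  The count is obtained by a subset
dynamic program over assignment masks (equivalent to, and cross-checked
against, brute-force enumeration), which is comfortably exact up to n = 10.

Critical values follow the two-sided convention of the standard tables:
the critical rho at two-sided level alpha is the smallest attainable rho
whose one-sided upper-tail probability is at most alpha / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial
from typing import Optional

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RankCorrelationResult",
    "CriticalValue",
    "spearman_rho",
    "exact_null_distribution",
    "exact_p_upper",
    "critical_value",
    "spearman_test",
]

_MAX_EXACT_N = 10


@dataclass(frozen=True)
class CriticalValue:
    """Attainable critical rho at a requested two-sided level.

    When no attainable rho meets the level (tiny n), ``attainable`` is False
    and ``min_level`` reports the smallest achievable one-sided tail
    probability, 1/n!.
    """

    n: int
    alpha: float
    attainable: bool
    rho_c: Optional[float] = None
    rho_c_rounded: Optional[float] = None
    tail_prob: Optional[float] = None
    min_level: Optional[float] = None


@dataclass(frozen=True)
class RankCorrelationResult:
    rho: float
    n: int
    p_upper: Optional[float] = None     # exact one-sided upper-tail prob
    critical: Optional[CriticalValue] = None

    @property
    def significant(self) -> Optional[bool]:
        if self.critical is None or not self.critical.attainable:
            return None
        return self.rho >= self.critical.rho_c - 1e-12


def spearman_rho(xs, ys) -> float:
    """Spearman correlation; d^2 shortcut when tie-free, rank PM otherwise."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1-d sequences of equal length")
    n = xs.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    rx = rankdata(xs, method="average")
    ry = rankdata(ys, method="average")
    tie_free = np.unique(xs).size == n and np.unique(ys).size == n
    if tie_free:
        s = float(np.sum((rx - ry) ** 2))
        return 1.0 - 6.0 * s / (n * (n * n - 1))
    return float(np.corrcoef(rx, ry)[0, 1])


def _enumerate_s_counts(n: int) -> np.ndarray:
    """counts[s] = number of permutations of 0..n-1 with sum (i - pi)^2 = s.

    Subset DP: process positions in order; the mask records which target
    ranks are already used.  States are (mask, running S); transitions add
    (i - j)^2 for each unused rank j.
    """
    s_max = n * (n * n - 1) // 3  # reversal permutation attains the maximum
    size = 1 << n
    dp: list[Optional[np.ndarray]] = [None] * size
    dp[0] = np.zeros(s_max + 1, dtype=np.int64)
    dp[0][0] = 1
    for mask in range(size):
        row = dp[mask]
        if row is None:
            continue
        i = bin(mask).count("1")  # next position to assign
        if i == n:
            continue
        for j in range(n):
            bit = 1 << j
            if mask & bit:
                continue
            d2 = (i - j) * (i - j)
            nxt = mask | bit
            if dp[nxt] is None:
                dp[nxt] = np.zeros(s_max + 1, dtype=np.int64)
            if d2 == 0:
                dp[nxt] += row
            else:
                dp[nxt][d2:] += row[: s_max + 1 - d2]
        dp[mask] = None  # free memory as soon as the state is expanded
    return dp[size - 1]


@lru_cache(maxsize=None)
def _null_table(n: int) -> tuple[np.ndarray, np.ndarray]:
    counts = _enumerate_s_counts(n)
    s_values = np.nonzero(counts)[0]
    return s_values.astype(np.int64), counts[s_values]


def exact_null_distribution(n: int):
    """Exact null distribution of rho for ``n`` untied observations.

    Returns a record array-like dict with attainable S values, the
    corresponding rho values, permutation counts and probabilities.
    """
    if not 3 <= n <= _MAX_EXACT_N:
        raise ValueError(f"exact enumeration supports 3 <= n <= {_MAX_EXACT_N}, got {n}")
    s_values, counts = _null_table(n)
    denom = n * (n * n - 1)
    return {
        "s": s_values.copy(),
        "rho": 1.0 - 6.0 * s_values / denom,
        "count": counts.copy(),
        "prob": counts / factorial(n),
    }


def exact_p_upper(rho: float, n: int) -> float:
    """Exact P(rho_null >= rho) from the permutation distribution.

    rho is mapped back to an S threshold; with tied data (rho computed from
    average ranks) this is an approximation against the tie-free null.
    """
    if not 3 <= n <= _MAX_EXACT_N:
        raise ValueError(f"exact tail supports 3 <= n <= {_MAX_EXACT_N}, got {n}")
    s_values, counts = _null_table(n)
    s_obs = (1.0 - rho) * n * (n * n - 1) / 6.0
    mask = s_values <= s_obs + 1e-9
    return float(counts[mask].sum() / factorial(n))


def critical_value(n: int, alpha: float) -> CriticalValue:
    """Smallest attainable rho with one-sided tail probability <= alpha/2.

    ``alpha`` is the two-sided level; the returned ``rho_c_rounded`` is the
    3-decimal table form.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 3 <= n <= _MAX_EXACT_N:
        raise ValueError(f"exact critical values support 3 <= n <= {_MAX_EXACT_N}")
    s_values, counts = _null_table(n)
    nfact = factorial(n)
    cum = np.cumsum(counts)  # P(S <= s) * n!  along ascending s
    tail = cum / nfact       # upper-tail prob of the corresponding rho
    ok = tail <= alpha / 2.0 + 1e-15
    if not np.any(ok):
        return CriticalValue(
            n=n, alpha=alpha, attainable=False, min_level=1.0 / nfact
        )
    idx = int(np.max(np.nonzero(ok)[0]))  # largest S, hence smallest rho
    denom = n * (n * n - 1)
    rho_c = 1.0 - 6.0 * float(s_values[idx]) / denom
    return CriticalValue(
        n=n,
        alpha=alpha,
        attainable=True,
        rho_c=rho_c,
        rho_c_rounded=round(rho_c, 3),
        tail_prob=float(tail[idx]),
    )


def spearman_test(xs, ys, alpha: float = 0.01) -> RankCorrelationResult:
    """rho plus exact significance machinery when n permits it."""
    rho = spearman_rho(xs, ys)
    n = len(xs)
    if 3 <= n <= _MAX_EXACT_N:
        return RankCorrelationResult(
            rho=rho,
            n=n,
            p_upper=exact_p_upper(rho, n),
            critical=critical_value(n, alpha),
        )
    return RankCorrelationResult(rho=rho, n=n)
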