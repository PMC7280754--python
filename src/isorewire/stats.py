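"""Shared statistical primitives used across the pipeline.

Rank tests, multiplicity corrections, correlation, an ordered-group trend
test and stable hypergeometric tails.  Wherever an established routine
exists (scipy, statsmodels) it is used under the hood; the hypergeometric
tails are evaluated in log-space so that gene-set-scale arguments do not
underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "bonferroni_adjust",
    "spearman_correlation",
    "hypergeometric_upper_tail",
    "hypergeometric_lower_tail",
    "jonckheere_terpstra_trend",
]

#: below this per-group size the Wilcoxon test enumerates the exact null
#: distribution (ties force the normal approximation regardless)
EXACT_THRESHOLD = 10


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_threshold: int = EXACT_THRESHOLD
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration when the smaller group has at most
    ``exact_threshold`` observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= exact_threshold and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"wilcoxon-rank-sum-{method}",
        n=(int(x.size), int(y.size)),
    )


def _check_pvalues(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr))):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    arr = _check_pvalues(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def bonferroni_adjust(p: Sequence[float]) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    arr = _check_pvalues(p)
    return np.minimum(arr * arr.size, 1.0)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with midranks for ties; p by t-approximation.

    A constant input vector leaves rho undefined; the result is returned with
    ``undefined=True`` rather than raising, so screening loops can keep going.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return TestResult(
            statistic=float("nan"), p_value=float("nan"), method="spearman",
            n=(int(xa.size),), undefined=True,
        )
    rho, p = sps.spearmanr(xa, ya)
    return TestResult(statistic=float(rho), p_value=float(p), method="spearman", n=(int(xa.size),))


def _check_hypergeom_args(N: int, K: int, n: int) -> None:
    if N < 0 or K < 0 or n < 0 or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric arguments: N={N}, K={K}, n={n}")


def hypergeometric_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log-space.

    N is the population size, K the number of marked items, n the draw size.
    """
    _check_hypergeom_args(N, K, n)
    if k < 0 or k > min(K, n):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return 1.0
    lo = max(k, max(0, K + n - N))
    hi = min(K, n)
    if lo > hi:
        return 0.0
    logp = sps.hypergeom.logpmf(np.arange(lo, hi + 1), N, K, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


def hypergeometric_lower_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X <= k) for X ~ Hypergeometric(N, K, n), in log-space."""
    _check_hypergeom_args(N, K, n)
    if k < max(0, K + n - N) - 1:
        return 0.0
    if k < 0:
        return 0.0
    if k >= min(K, n):
        return 1.0
    lo = max(0, K + n - N)
    logp = sps.hypergeom.logpmf(np.arange(lo, k + 1), N, K, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    stat = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            u = groups[i][:, None]
            v = groups[j][None, :]
            stat += np.sum(v > u) + 0.5 * np.sum(v == u)
    return float(stat)


def jonckheere_terpstra_trend(
    groups: Sequence[Sequence[float]],
    method: str = "permutation",
    n_permutations: int = 2000,
    rng: np.random.Generator | int | None = 0,
) -> TestResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    The statistic counts concordant cross-group pairs (ties count one half).
    The two-sided p-value comes from a seeded permutation null by default, or
    from the no-ties normal approximation (``method="normal"``).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("need at least 3 ordered groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    sizes = np.array([a.size for a in arrays])
    stat = _jt_statistic(arrays)
    total = int(sizes.sum())
    mean = (total**2 - np.sum(sizes**2)) / 4.0

    if method == "normal":
        var = (total**2 * (2 * total + 3) - np.sum(sizes**2 * (2 * sizes + 3))) / 72.0
        if var <= 0:
            return TestResult(stat, 1.0, "jonckheere-terpstra-normal", tuple(int(s) for s in sizes))
        z = (stat - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        return TestResult(stat, float(min(p, 1.0)), "jonckheere-terpstra-normal", tuple(int(s) for s in sizes))
    if method != "permutation":
        raise ValueError(f"unknown method: {method!r}")

    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pooled = np.concatenate(arrays)
    bounds = np.cumsum(sizes)[:-1]
    count = 0
    for _ in range(n_permutations):
        perm = gen.permutation(pooled)
        perm_groups = np.split(perm, bounds)
        if abs(_jt_statistic(perm_groups) - mean) >= abs(stat - mean) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return TestResult(stat, float(p), "jonckheere-terpstra-permutation", tuple(int(s) for s in sizes))
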