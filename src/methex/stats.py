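"""Exact small-sample statistics used throughout the pipeline.

With 6 first-trimester vs 5 third-trimester methylomes (and 5 vs 4
transcriptomes) the group sizes are small enough that exact tests are both
feasible and preferable to large-sample approximations: the exact two-sided
Mann-Whitney U test (permutation-exact under ties), Benjamini-Hochberg
step-up adjustment, and the exact two-sided binomial test used for
sign-concordance calls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.stats import binom, binomtest, norm, rankdata
from statsmodels.stats.multitest import multipletests

#: enumeration is used whenever C(n1+n2, n1) does not exceed this
EXACT_LIMIT = 200_000


class Method(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided test: the statistic (U or k), its p-value,
    how the p-value was computed, and the sample sizes."""

    statistic: float
    p_value: float
    method: Method
    n1: int
    n2: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@lru_cache(maxsize=64)
def _combination_matrix(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets of range(n), one subset per row."""
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def _u_statistic(ranks_x: np.ndarray, n1: int, n2: int) -> float:
    # U for sample x from its mid-rank sum
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def exact_mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by full enumeration.

    U is computed with mid-ranks for ties.  When C(n1+n2, n1) <= EXACT_LIMIT
    the null distribution of U is obtained by enumerating every assignment of
    the pooled observed values to the two groups (permutation-exact, hence
    valid under ties); the two-sided p-value is min(1, 2 * smaller one-sided
    tail).  Larger problems fall back to the normal approximation with tie
    and continuity corrections.

    Parameters
    ----------
    x, y : array-like
        The two samples; both must be non-empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks
    u_obs = _u_statistic(ranks[:n1], n1, n2)

    n_assign = comb(n, n1)
    if n_assign <= EXACT_LIMIT:
        idx = _combination_matrix(n, n1)
        rank_sums = ranks[idx].sum(axis=1)
        u_all = rank_sums - n1 * (n1 + 1) / 2.0
        # permutation tails at the observed U (tolerance for float rank sums)
        eps = 1e-9
        p_low = np.count_nonzero(u_all <= u_obs + eps) / n_assign
        p_high = np.count_nonzero(u_all >= u_obs - eps) / n_assign
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(u_obs, p, Method.EXACT, n1, n2)

    # normal approximation with tie correction and continuity correction
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values tied
        return TestResult(u_obs, 1.0, Method.NORMAL_APPROX, n1, n2)
    z = (u_obs - mu - np.sign(u_obs - mu) * 0.5) / sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(u_obs, p, Method.NORMAL_APPROX, n1, n2)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Sorted ascending, adj_(i) = min_{j>=i}(p_(j) * m / j), capped at 1,
    returned in the input order.  Delegates to statsmodels.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials.

    For the symmetric null p0 = 0.5 the two-sided p-value is the doubling
    rule min(1, 2 * min(P(X<=k), P(X>=k))); for p0 != 0.5 the
    minimum-likelihood definition (sum of all outcomes no more probable
    than k) is used.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if p0 == 0.5:
        p_low = binom.cdf(k, n, p0)
        p_high = binom.sf(k - 1, n, p0)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        p = binomtest(k, n, p0, alternative="two-sided").pvalue
    return TestResult(float(k), float(p), Method.EXACT, n)
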