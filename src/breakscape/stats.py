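"""Small-sample hypothesis tests used throughout the pipeline.

The exact-path logic (rank enumeration, hypergeometric/binomial tail
summation, median dichotomization) lives here; scipy supplies only the
underlying probability distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .core import PreconditionError

TWO, LESS, GREATER = "two", "less", "greater"

# relative tolerance for "as extreme as observed" tie comparisons in
# exact two-sided tests (Fisher, binomial)
_TIE_RTOL = 1e-7


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int = 0
    n2: int = 0
    tails: str = TWO
    degenerate: bool = False
    exact: bool = True

    def __post_init__(self) -> None:
        # clamp floating-point overshoot, never mask a real defect
        if -1e-12 <= self.p_value <= 1 + 1e-12:
            self.p_value = min(1.0, max(0.0, self.p_value))
        else:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")

    def to_tsv_row(self) -> str:
        return (
            f"{self.method}\t{self.statistic:.6g}\t{self.p_value:.6g}"
            f"\t{self.n1}\t{self.n2}"
        )


def _check_tails(tails: str) -> None:
    if tails not in (TWO, LESS, GREATER):
        raise PreconditionError(f"tails must be one of two/less/greater, got {tails!r}")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    tails: str = TWO,
    exact_limit: int = 12,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration of all rank assignments when
    ``n1 + n2 <= exact_limit`` and there are no ties; otherwise a normal
    approximation with midranks, tie-corrected variance and continuity
    correction. One-sided ``greater`` means x tends larger than y.
    """
    _check_tails(tails)
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise PreconditionError("wilcoxon_rank_sum requires two non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())  # rank sum of x
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= exact_limit and not has_ties:
        # enumerate all C(n, n1) assignments of the integer ranks to x
        n = n1 + n2
        sums = np.array([sum(c) for c in combinations(range(1, n + 1), n1)], dtype=float)
        total = len(sums)
        mu = n1 * (n + 1) / 2.0
        p_ge = np.count_nonzero(sums >= w) / total
        p_le = np.count_nonzero(sums <= w) / total
        if tails == GREATER:
            p = p_ge
        elif tails == LESS:
            p = p_le
        else:
            # null distribution symmetric about mu when there are no ties
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(w, p, "wilcoxon_rank_sum_exact", n1, n2, tails)

    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(w, 1.0, "wilcoxon_rank_sum_normal", n1, n2, tails,
                          degenerate=True, exact=False)
    sd = sqrt(var)
    d = w - mu
    if tails == GREATER:
        z = (d - 0.5) / sd
        p = float(sps.norm.sf(z))
    elif tails == LESS:
        z = (d + 0.5) / sd
        p = float(sps.norm.cdf(z))
    else:
        z = (abs(d) - 0.5) / sd
        p = float(2.0 * sps.norm.sf(max(z, 0.0)))
        p = min(1.0, p)
    return TestResult(w, p, "wilcoxon_rank_sum_normal", n1, n2, tails, exact=False)


def fisher_exact_2x2(table, tails: str = TWO) -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided p is the sum of hypergeometric probabilities of all tables
    (with the observed margins) whose probability is <= the observed
    table's, within relative tolerance 1e-7 for ties.
    """
    _check_tails(tails)
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise PreconditionError("fisher_exact_2x2 needs a 2x2 table")
    if np.any(t < 0):
        raise PreconditionError("table cells must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    if N == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        # a zero margin leaves only one possible table
        odds = _odds_ratio(a, b, c, d)
        return TestResult(odds, 1.0, "fisher_exact", r1, r2, tails, degenerate=True)
    rv = sps.hypergeom(N, r1, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    if tails == GREATER:
        p = float(pmf[support >= a].sum())
    elif tails == LESS:
        p = float(pmf[support <= a].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
    return TestResult(_odds_ratio(a, b, c, d), min(1.0, p), "fisher_exact", r1, r2, tails)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def chi_square_gof(observed: Sequence[float], expected: Sequence[float]) -> TestResult:
    """Pearson's chi-square goodness-of-fit test (df = k - 1)."""
    o = np.asarray(list(observed), dtype=float)
    e = np.asarray(list(expected), dtype=float)
    if o.shape != e.shape or o.ndim != 1:
        raise PreconditionError("observed and expected must be equal-length vectors")
    if np.any(e <= 0):
        raise PreconditionError("expected counts must be positive")
    if np.any(o < 0):
        raise PreconditionError("observed counts must be non-negative")
    stat = float(np.sum((o - e) ** 2 / e))
    df = len(o) - 1
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return TestResult(stat, p, "chi_square_gof", len(o), df, TWO, exact=False)


def moods_median_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mood's median test.

    Both samples are dichotomized at the pooled grand median (values
    strictly greater vs not greater; ties at the median count as "not
    greater"), then Fisher's exact test is applied to the 2x2 table.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise PreconditionError("moods_median_test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "moods_median", len(x), len(y), TWO, degenerate=True)
    m = float(np.median(pooled))
    gx, gy = int(np.sum(x > m)), int(np.sum(y > m))
    table = [[gx, len(x) - gx], [gy, len(y) - gy]]
    res = fisher_exact_2x2(table, TWO)
    return TestResult(res.statistic, res.p_value, "moods_median", len(x), len(y), TWO,
                      degenerate=res.degenerate)


def binomial_test(k: int, n: int, p0: float = 0.5, tails: str = TWO) -> TestResult:
    """Exact binomial test of k successes out of n against rate p0.

    Two-sided p sums the probabilities of all outcomes no more likely
    than the observed one.
    """
    _check_tails(tails)
    if n <= 0:
        raise PreconditionError("binomial_test requires n >= 1")
    if not (0 <= k <= n):
        raise PreconditionError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise PreconditionError("need 0 < p0 < 1")
    support = np.arange(n + 1)
    pmf = sps.binom.pmf(support, n, p0)
    if tails == GREATER:
        p = float(pmf[support >= k].sum())
    elif tails == LESS:
        p = float(pmf[support <= k].sum())
    else:
        p = float(pmf[pmf <= pmf[k] * (1 + _TIE_RTOL)].sum())
    return TestResult(float(k) / n, min(1.0, p), "binomial_exact", k, n, tails)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-scaled p-value, capped at 1."""
    if n_comparisons < 1:
        raise PreconditionError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)
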