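"""Nonparametric statistics for grouped spread areas.

Everything here is implemented directly (no delegation to scipy.stats) so
small-sample behavior is exact and testable: median/IQR with the
linear-interpolation quantile convention, the two-sided independent-samples
Wilcoxon rank-sum (Mann–Whitney) test with complete enumeration for small
samples, Spearman correlation on mid-ranks, and ordinary least squares.

Quantile convention: order statistic at position ``p·(n−1)`` with linear
interpolation between neighbours.  IQRs depend on this choice, so it is
fixed here and used everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrelationResult",
    "RegressionFit",
    "median_iqr",
    "wilcoxon_ranksum",
    "spearman",
    "linear_fit",
    "midranks",
]

#: n1+n2 at or below which the exact enumeration is used in ``auto`` mode.
EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class GroupSummary:
    group: tuple[float, float] | str | None
    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class TestResult:
    statistic: float  # rank sum of the first sample
    p_value: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def _quantile(sorted_values: np.ndarray, p: float) -> float:
    """Linear interpolation between order statistics at position p·(n−1)."""
    n = len(sorted_values)
    pos = p * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return float(sorted_values[lo] * (1 - frac) + sorted_values[hi] * frac)


def median_iqr(values: Sequence[float], group=None) -> GroupSummary:
    """Median and quartiles of a sample (see module docstring for the
    quantile convention)."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("median_iqr needs at least one value")
    return GroupSummary(
        group=group,
        n=int(arr.size),
        median=_quantile(arr, 0.5),
        q1=_quantile(arr, 0.25),
        q3=_quantile(arr, 0.75),
    )


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean of their rank range."""
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="mergesort")
    ranks = np.empty(arr.size, dtype=float)
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and arr[order[j + 1]] == arr[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # mean of ranks i+1..j+1
        i = j + 1
    return ranks


def _exact_two_sided_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided p by complete enumeration of all C(n, n1) group assignments.

    Works on the actual mid-ranks, so ties are handled by permutation of the
    observed rank vector.
    """
    n = len(ranks)
    mu = n1 * (n + 1) / 2.0  # total rank sum is fixed at n(n+1)/2
    dev = abs(w_obs - mu)
    extreme = 0
    total = 0
    for combo in combinations(range(n), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def _normal_approx_p(ranks: np.ndarray, n1: int, n2: int, w_obs: float) -> float:
    """Normal approximation with tie-corrected variance and continuity
    correction."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    # tie correction: sum over tie groups of (t^3 - t)
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts.astype(float) ** 3) - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, math.erfc(z / math.sqrt(2.0)))


def wilcoxon_ranksum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided independent-samples rank-sum (Mann–Whitney) test.

    Mid-ranks for ties.  ``mode='exact'`` enumerates all C(n1+n2, n1)
    assignments (used automatically when n1+n2 ≤ 20); ``'approx'`` uses the
    tie-corrected normal approximation with continuity correction.  Samples
    that are identical everywhere yield p = 1 with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples need at least one observation")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    w_obs = float(ranks[:n1].sum())

    if np.all(pooled == pooled[0]):
        method = "exact" if (mode != "approx" and n1 + n2 <= EXACT_ENUMERATION_LIMIT) else "normal_approx"
        return TestResult(w_obs, 1.0, method, n1, n2, degenerate=True)

    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= EXACT_ENUMERATION_LIMIT)
    if use_exact:
        p = _exact_two_sided_p(ranks, n1, w_obs)
        method = "exact"
    else:
        p = _normal_approx_p(ranks, n1, n2, w_obs)
        method = "normal_approx"
    return TestResult(w_obs, float(p), method, n1, n2)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Equals ``1 − 6Σd²/(n(n²−1))`` when there are no ties.  Constant input is
    an error — the correlation is undefined, not zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant variable")
    rx = midranks(x)
    ry = midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
    return CorrelationResult(r=max(-1.0, min(1.0, r)), n=n)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares y = a·x + b with r² = 1 − SSres/SStot.

    Constant x is a singular fit (error); constant y yields slope 0 and, by
    convention, r² = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("linear_fit needs >= 2 paired observations")
    xm = x - x.mean()
    sxx = float((xm**2).sum())
    if sxx == 0:
        raise ValueError("singular fit: x is constant")
    slope = float((xm * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return RegressionFit(slope=slope, intercept=intercept, r_squared=0.0, n=len(x))
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r2, n=len(x))
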