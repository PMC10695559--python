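"""Nonparametric group tests and interval estimators.

The rank tests are implemented natively (the tie conventions are part of the
contract and are cross-checked against scipy in the test suite); only the
reference chi-square and normal distributions come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

from .errors import FosnetError

__all__ = ["TestResult", "kruskal_wallis", "mann_whitney", "mean_difference_ci"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise FosnetError(f"p-value {self.p_value} outside [0, 1]")
        if self.statistic < 0:
            raise FosnetError(f"statistic {self.statistic} is negative")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
            "n_per_group": list(self.n_per_group),
        }


def _rank_average(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j + 2) / 2.0  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _tie_counts(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square, df = k-1.

    All values identical across all groups yields H = 0, p = 1.
    """
    if len(samples) < 2:
        raise FosnetError("need at least two samples")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for a in arrays:
        if len(a) == 0:
            raise FosnetError("empty sample")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = _rank_average(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r_sum = ranks[start : start + len(a)].sum()
        h += r_sum**2 / len(a)
        start += len(a)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    ties = _tie_counts(pooled)
    correction = 1.0 - (ties**3 - ties).sum() / (n_total**3 - n_total)
    df = len(samples) - 1
    if correction == 0.0:  # every value identical
        return TestResult(0.0, df, 1.0, "kruskal-wallis", tuple(len(a) for a in arrays))
    h = max(h / correction, 0.0)
    p = float(chi2.sf(h, df))
    return TestResult(float(h), df, p, "kruskal-wallis", tuple(len(a) for a in arrays))


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of rank arrangements with each U value, for sample sizes m, n.

    counts[u] is the number of partitions of u into at most m parts, each at
    most n (the classic Mann-Whitney recurrence).
    """
    if m == 0 or n == 0:
        return (1,)
    prev = _u_counts(m - 1, n)  # at most m-1 parts
    max_u = m * n
    counts = [0] * (max_u + 1)
    # counts(m, n, u) = counts(m, n-1, u) + counts(m-1, n, u-n)
    smaller = _u_counts(m, n - 1)
    for u in range(max_u + 1):
        c = smaller[u] if u < len(smaller) else 0
        if u >= n:
            c += prev[u - n] if u - n < len(prev) else 0
        counts[u] = c
    return tuple(counts)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U for sample ``a``.

    U counts pairs with a > b plus half of the ties. The p-value is exact
    (enumeration) when the combined size is <= 20 and there are no ties;
    otherwise a tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise FosnetError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _rank_average(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    u_b = n_a * n_b - u_a
    ties = _tie_counts(pooled)
    has_ties = bool((ties > 1).any())
    if n_a + n_b <= 20 and not has_ties:
        counts = _u_counts(n_a, n_b)
        total = sum(counts)
        u_small = int(round(min(u_a, u_b)))
        p = 2.0 * sum(counts[: u_small + 1]) / total
        p = min(p, 1.0)
        method = "mann-whitney (exact)"
    else:
        n = n_a + n_b
        mu = n_a * n_b / 2.0
        tie_term = (ties**3 - ties).sum() / (n * (n - 1))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:  # all values identical
            return TestResult(u_a, None, 1.0, "mann-whitney (asymptotic)", (n_a, n_b))
        # continuity correction toward the mean
        z = (u_a - mu - 0.5 * np.sign(u_a - mu)) / np.sqrt(sigma2)
        p = min(2.0 * float(norm.sf(abs(z))), 1.0)
        method = "mann-whitney (asymptotic)"
    return TestResult(u_a, None, p, method, (n_a, n_b))


def mean_difference_ci(
    sample: Sequence[float], reference: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Mean and percentile interval of the differences sample_i - reference.

    Quantiles use linear interpolation between order statistics (type 7).
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 2:
        raise FosnetError("need at least two values")
    diffs = sample - reference
    tail = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(diffs, [tail, 100.0 - tail])
    return float(diffs.mean()), float(lo), float(hi)
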