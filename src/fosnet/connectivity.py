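"""Per-group interregional Pearson correlation matrices and group comparisons.

Matrices follow the convention that the diagonal is zeroed; all downstream
consumers (thresholding, mean-r comparisons) read the upper triangle only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .counts import CountTable
from .errors import DegenerateVarianceError, FosnetError
from .scheme import RegionScheme
from .stats import TestResult, kruskal_wallis, mann_whitney

__all__ = [
    "CorrelationMatrix",
    "GroupComparison",
    "correlation_matrix",
    "offdiagonal_values",
    "collection_values",
    "compare_group_r",
]

CollectionRule = Literal["incident", "within"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric region-by-region Pearson r matrix with a zeroed diagonal."""

    group: str
    regions: tuple[str, ...]
    r: np.ndarray
    n_animals: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "regions", tuple(self.regions))
        p = len(self.regions)
        if r.shape != (p, p):
            raise FosnetError(f"matrix shape {r.shape} does not match {p} regions")
        if not np.allclose(r, r.T, atol=1e-12):
            raise FosnetError("correlation matrix is not symmetric")
        if np.any(np.diag(r) != 0.0):
            raise FosnetError("diagonal must be zeroed")
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise FosnetError("|r| exceeds 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.regions, columns=self.regions)

    def value(self, a: str, b: str) -> float:
        return float(self.r[self.regions.index(a), self.regions.index(b)])


def correlation_matrix(table: CountTable, group: str) -> CorrelationMatrix:
    """Sample Pearson r between every pair of regions across a group's animals."""
    data = table.group_counts(group)
    n = len(data)
    if n < 3:
        raise FosnetError(f"group {group!r} has {n} animals; need at least 3")
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise DegenerateVarianceError(
            f"zero variance in group {group!r} for region {data.columns[flat[0]]!r}"
        )
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return CorrelationMatrix(group=group, regions=tuple(data.columns), r=r, n_animals=n)


def offdiagonal_values(m: CorrelationMatrix) -> np.ndarray:
    """Upper-triangle r values in row-major (i<j) order; p(p-1)/2 of them."""
    iu = np.triu_indices(len(m.regions), k=1)
    return m.r[iu]


def pair_labels(regions: Sequence[str]) -> list[tuple[str, str]]:
    """Region-name pairs in the same order as :func:`offdiagonal_values`."""
    return [
        (regions[i], regions[j])
        for i in range(len(regions))
        for j in range(i + 1, len(regions))
    ]


def collection_values(
    m: CorrelationMatrix,
    scheme: RegionScheme,
    collection: str,
    rule: CollectionRule = "incident",
) -> np.ndarray:
    """r values for pairs belonging to a named collection.

    rule="incident" keeps pairs with at least one endpoint in the collection
    (the default; small collections still yield usable samples);
    rule="within" keeps only pairs with both endpoints inside it.
    """
    members = set(scheme.collection(collection))
    vals = offdiagonal_values(m)
    labels = pair_labels(m.regions)
    if rule == "incident":
        keep = [i for i, (a, b) in enumerate(labels) if a in members or b in members]
    elif rule == "within":
        keep = [i for i, (a, b) in enumerate(labels) if a in members and b in members]
    else:
        raise ValueError(f"unknown collection rule {rule!r}")
    return vals[keep]


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis omnibus plus (when significant) pairwise Mann-Whitney tests."""

    labels: tuple[str, ...]
    medians: dict[str, float]
    omnibus: TestResult
    pairwise: dict[tuple[str, str], TestResult]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "medians": self.medians,
            "omnibus": self.omnibus.to_dict(),
            "pairwise": {
                f"{a} vs {b}": res.to_dict() for (a, b), res in self.pairwise.items()
            },
        }


def _compare_samples(
    labels: Sequence[str], samples: Sequence[np.ndarray], alpha: float = 0.05
) -> GroupComparison:
    for lab, s in zip(labels, samples):
        if len(s) == 0:
            raise FosnetError(f"empty value list for {lab!r}")
    omnibus = kruskal_wallis([list(s) for s in samples])
    pairwise: dict[tuple[str, str], TestResult] = {}
    if omnibus.p_value < alpha:
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                pairwise[(labels[i], labels[j])] = mann_whitney(
                    list(samples[i]), list(samples[j])
                )
    medians = {lab: float(np.median(s)) for lab, s in zip(labels, samples)}
    return GroupComparison(
        labels=tuple(labels), medians=medians, omnibus=omnibus, pairwise=pairwise
    )


def compare_group_r(
    matrices: Sequence[CorrelationMatrix],
    scheme: RegionScheme | None = None,
    collection: str = "all",
    rule: CollectionRule = "incident",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare groups' r-value distributions (all pairs, or one collection).

    The matrix entries are treated as independent samples, mirroring the
    source procedure; this is descriptive rather than strictly inferential.
    Pairwise p-values are reported unadjusted.
    """
    if len(matrices) < 2:
        raise FosnetError("need at least two matrices to compare")
    if collection == "all":
        samples = [offdiagonal_values(m) for m in matrices]
    else:
        if scheme is None:
            raise FosnetError("a scheme is required for collection comparisons")
        samples = [collection_values(m, scheme, collection, rule) for m in matrices]
    labels = [m.group for m in matrices]
    return _compare_samples(labels, samples, alpha=alpha)
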