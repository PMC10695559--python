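"""Per-animal regional count tables: reading, writing, and control normalization.

A count table holds one non-negative number per animal and region (the
per-animal mean over bilateral slices) plus a group label per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .errors import (
    CountValueError,
    DegenerateControlError,
    LabelError,
    SchemaError,
    StateError,
    UndefinedIndexError,
)
from .scheme import RegionScheme

__all__ = [
    "CountTable",
    "BehaviorRecord",
    "read_counts",
    "write_counts",
    "read_behavior",
    "normalize_to_control",
    "generalization_index",
]

META_COLUMNS = ("animal_id", "group")


@dataclass
class CountTable:
    """Validated per-animal counts for every region of a scheme.

    ``frame`` is indexed by animal_id with a ``group`` column followed by one
    float column per region, in scheme order.
    """

    scheme: RegionScheme
    frame: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [r for r in self.scheme.regions if r not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing region columns: {missing}")
        if "group" not in self.frame.columns:
            raise SchemaError("missing 'group' column")
        # canonical column order
        self.frame = self.frame[["group", *self.scheme.regions]]
        values = self.frame[list(self.scheme.regions)]
        if values.isna().any().any():
            bad = values.isna().stack()
            animal, region = bad[bad].index[0]
            raise CountValueError(f"non-numeric count for animal {animal!r}, region {region!r}")
        if (values.to_numpy() < 0).any():
            neg = (values < 0).stack()
            animal, region = neg[neg].index[0]
            raise CountValueError(
                f"negative count {values.loc[animal, region]!r} for animal {animal!r}, "
                f"region {region!r}"
            )

    @property
    def animals(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.frame["group"]:
            seen.setdefault(g, None)
        return tuple(seen)

    def group_counts(self, group: str) -> pd.DataFrame:
        """Region columns for one group (animals x regions)."""
        if group not in set(self.frame["group"]):
            raise LabelError(f"no animals with group label {group!r}")
        sub = self.frame[self.frame["group"] == group]
        return sub[list(self.scheme.regions)]

    def n_animals(self, group: str) -> int:
        return int((self.frame["group"] == group).sum())


def read_counts(
    path,
    scheme: RegionScheme,
    groups: Sequence[str] | None = None,
) -> CountTable:
    """Read a counts CSV (animal_id, group, one column per region).

    Region columns are matched case-sensitively against the scheme. When
    ``groups`` is given, any label outside it raises :class:`LabelError`.
    """
    raw = pd.read_csv(path, dtype={"animal_id": str, "group": str})
    for col in META_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    missing = [r for r in scheme.regions if r not in raw.columns]
    if missing:
        raise SchemaError(f"missing region columns: {missing}")
    if raw["animal_id"].duplicated().any():
        dup = raw.loc[raw["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise SchemaError(f"duplicate animal_id {dup!r}")
    if groups is not None:
        unknown = sorted(set(raw["group"]) - set(groups))
        if unknown:
            raise LabelError(f"unknown group labels: {unknown}")
    frame = raw.set_index("animal_id")
    for region in scheme.regions:
        coerced = pd.to_numeric(frame[region], errors="coerce")
        bad = coerced.isna() & frame[region].notna()
        if bad.any():
            animal = bad[bad].index[0]
            raise CountValueError(
                f"non-numeric count {frame.loc[animal, region]!r} for animal "
                f"{animal!r}, region {region!r}"
            )
        frame[region] = coerced.astype(float)
    return CountTable(scheme=scheme, frame=frame, normalized=False)


def write_counts(table: CountTable, path) -> None:
    """Write a counts CSV that :func:`read_counts` round-trips exactly."""
    out = table.frame.reset_index()
    out = out.rename(columns={out.columns[0]: "animal_id"})
    out.to_csv(path, index=False, float_format="%.17g")


def normalize_to_control(table: CountTable, control_group: str) -> CountTable:
    """Divide every count by the control group's per-region arithmetic mean.

    After normalization the control group's mean is exactly 1 in every region.
    """
    if table.normalized:
        raise StateError("table is already normalized")
    control = table.group_counts(control_group)
    means = control.mean(axis=0)
    zero = means[means <= 0]
    if len(zero):
        raise DegenerateControlError(
            f"control mean is zero for region(s): {list(zero.index)}"
        )
    frame = table.frame.copy()
    frame[list(table.scheme.regions)] = frame[list(table.scheme.regions)] / means
    return replace(table, frame=frame, normalized=True)


@dataclass(frozen=True)
class BehaviorRecord:
    """Percent time freezing in the trained (A) and novel (B) contexts."""

    animal_id: str
    freezing_testA: float
    freezing_testB: float

    def __post_init__(self) -> None:
        for name in ("freezing_testA", "freezing_testB"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise CountValueError(f"{name}={v!r} outside [0, 100]")


def read_behavior(path) -> list[BehaviorRecord]:
    raw = pd.read_csv(path, dtype={"animal_id": str})
    for col in ("animal_id", "freezing_testA", "freezing_testB"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    return [
        BehaviorRecord(row.animal_id, float(row.freezing_testA), float(row.freezing_testB))
        for row in raw.itertuples(index=False)
    ]


def generalization_index(rec: BehaviorRecord) -> float:
    """Freezing in the novel context as a fraction of total freezing, B/(A+B)."""
    total = rec.freezing_testA + rec.freezing_testB
    if total == 0:
        raise UndefinedIndexError(f"animal {rec.animal_id!r}: total freezing is zero")
    return rec.freezing_testB / total
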