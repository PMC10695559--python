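"""Region schemes: the ordered node set and its named collections.

The region order declared here is the canonical row/column order of every
correlation matrix and metric table produced downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import SchemaError

__all__ = ["RegionScheme", "default_scheme", "DEFAULT_REGIONS", "DEFAULT_COLLECTIONS"]

DEFAULT_REGIONS = (
    "DG", "CA3", "CA1", "BLA", "CeA", "RSC", "IL", "PL", "Cg1", "Cg2", "Re", "PV",
)

DEFAULT_COLLECTIONS = {
    "Amyg": ("BLA", "CeA"),
    "HPC": ("DG", "CA3", "CA1"),
    "PFC": ("PL", "IL", "Cg1", "Cg2"),
    "Other": ("RSC", "PV", "Re"),
}


@dataclass(frozen=True)
class RegionScheme:
    """An ordered list of region names plus disjoint named collections.

    Invariants (checked on construction): collections are pairwise disjoint,
    every collection member is a declared region, and the union of the
    collections equals the region list.
    """

    regions: tuple[str, ...]
    collections: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(
            self, "collections", {k: tuple(v) for k, v in self.collections.items()}
        )
        if len(set(self.regions)) != len(self.regions):
            raise SchemaError("duplicate region names in scheme")
        seen: set[str] = set()
        for name, members in self.collections.items():
            for m in members:
                if m not in self.regions:
                    raise SchemaError(f"collection {name!r} references unknown region {m!r}")
                if m in seen:
                    raise SchemaError(f"region {m!r} appears in more than one collection")
                seen.add(m)
        if self.collections and seen != set(self.regions):
            missing = sorted(set(self.regions) - seen)
            raise SchemaError(f"collections do not cover regions: missing {missing}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def index(self, region: str) -> int:
        return self.regions.index(region)

    def collection(self, name: str) -> tuple[str, ...]:
        if name not in self.collections:
            raise KeyError(f"unknown collection {name!r}")
        return self.collections[name]

    @classmethod
    def from_yaml(cls, path) -> "RegionScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "regions" not in doc:
            raise SchemaError("scheme file must be a mapping with a 'regions' key")
        return cls(
            regions=tuple(doc["regions"]),
            collections={k: tuple(v) for k, v in (doc.get("collections") or {}).items()},
        )

    def to_yaml(self, path) -> None:
        doc = {
            "regions": list(self.regions),
            "collections": {k: list(v) for k, v in self.collections.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_scheme() -> RegionScheme:
    """The 12-region scheme with the Amyg/HPC/PFC/Other collections."""
    return RegionScheme(regions=DEFAULT_REGIONS, collections=DEFAULT_COLLECTIONS)


def _validate_subset(scheme: RegionScheme, regions: Sequence[str]) -> None:
    unknown = [r for r in regions if r not in scheme.regions]
    if unknown:
        raise SchemaError(f"regions not in scheme: {unknown}")
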