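"""Synthetic cohorts with planted interregional correlation structure.

A latent Gaussian copula with lognormal margins: each group draws animal
vectors from a multivariate normal with the planted correlation matrix, then
maps every margin to a positive count scale parameterized by a region mean
and coefficient of variation. Counts are positive and right-skewed, and the
latent Pearson structure transfers approximately to the count scale (the
test suite quantifies the transfer at large n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .counts import CountTable
from .errors import ConstructionError, FosnetError
from .scheme import RegionScheme, default_scheme

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "block_correlation",
    "generate_cohort",
    "paperlike_config",
    "PRESETS",
]

PSD_TOL = 1e-10


def _check_psd(matrix: np.ndarray, what: str = "correlation matrix") -> None:
    eigvals = np.linalg.eigvalsh(matrix)
    if eigvals.min() < -PSD_TOL:
        raise ConstructionError(
            f"{what} is not positive semidefinite (min eigenvalue {eigvals.min():.3g}); "
            "try a smaller within/between contrast"
        )


@dataclass(frozen=True)
class GroupSpec:
    """One group's size, count-scale parameters, and planted latent correlation."""

    name: str
    n_animals: int
    region_means: Mapping[str, float]
    region_cv: Mapping[str, float]
    latent_correlation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "latent_correlation", np.asarray(self.latent_correlation, dtype=float)
        )
        if self.n_animals < 3:
            raise FosnetError(f"group {self.name!r}: need at least 3 animals")
        for region, mean in self.region_means.items():
            if mean <= 0:
                raise FosnetError(f"group {self.name!r}: mean for {region!r} must be > 0")
        r = self.latent_correlation
        if not np.allclose(r, r.T, atol=1e-12) or not np.allclose(np.diag(r), 1.0):
            raise ConstructionError(
                f"group {self.name!r}: latent correlation must be symmetric with unit diagonal"
            )
        _check_psd(r, f"group {self.name!r} latent correlation")


@dataclass(frozen=True)
class SyntheticConfig:
    scheme: RegionScheme
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        p = self.scheme.n_regions
        for g in self.groups:
            if g.latent_correlation.shape != (p, p):
                raise FosnetError(
                    f"group {g.name!r}: latent correlation shape "
                    f"{g.latent_correlation.shape} != ({p}, {p})"
                )
            missing = [r for r in self.scheme.regions if r not in g.region_means]
            if missing:
                raise FosnetError(f"group {g.name!r}: missing means for {missing}")

    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "scheme": {
                "regions": list(self.scheme.regions),
                "collections": {k: list(v) for k, v in self.scheme.collections.items()},
            },
            "groups": [
                {
                    "name": g.name,
                    "n_animals": g.n_animals,
                    "region_means": {k: float(v) for k, v in g.region_means.items()},
                    "region_cv": {k: float(v) for k, v in g.region_cv.items()},
                    "latent_correlation": np.round(g.latent_correlation, 12).tolist(),
                }
                for g in self.groups
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        scheme = RegionScheme(
            regions=tuple(doc["scheme"]["regions"]),
            collections={
                k: tuple(v) for k, v in (doc["scheme"].get("collections") or {}).items()
            },
        )
        groups = tuple(
            GroupSpec(
                name=g["name"],
                n_animals=int(g["n_animals"]),
                region_means=g["region_means"],
                region_cv=g["region_cv"],
                latent_correlation=np.asarray(g["latent_correlation"], dtype=float),
            )
            for g in doc["groups"]
        )
        return cls(scheme=scheme, groups=groups, seed=int(doc.get("seed", 0)))


def block_correlation(
    scheme: RegionScheme,
    within: float,
    between: float,
    blocks: Sequence[Sequence[str]],
) -> np.ndarray:
    """Correlation matrix with r=within inside each block, r=between elsewhere."""
    if not 0.0 <= between <= within < 1.0:
        raise ConstructionError(
            f"need 0 <= between <= within < 1, got within={within}, between={between}"
        )
    p = scheme.n_regions
    index = {r: i for i, r in enumerate(scheme.regions)}
    seen: set[str] = set()
    r = np.full((p, p), float(between))
    for block in blocks:
        for region in block:
            if region not in index:
                raise FosnetError(f"unknown region {region!r} in block")
            if region in seen:
                raise ConstructionError(f"region {region!r} appears in two blocks")
            seen.add(region)
        ids = [index[region] for region in block]
        r[np.ix_(ids, ids)] = within
    np.fill_diagonal(r, 1.0)
    _check_psd(r, "block correlation matrix")
    return r


def _lognormal_margin(z: np.ndarray, mean: float, cv: float) -> np.ndarray:
    """Map standard-normal draws to a lognormal with the given mean and CV."""
    if cv <= 0:
        return np.full_like(z, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * z)


def generate_cohort(config: SyntheticConfig) -> CountTable:
    """Draw a CountTable with each group's planted correlation structure.

    Deterministic per seed: the same config always yields the same table.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    rows = []
    index = []
    for g in config.groups:
        z = rng.multivariate_normal(
            mean=np.zeros(scheme.n_regions),
            cov=g.latent_correlation,
            size=g.n_animals,
            method="eigh",
        )
        counts = np.empty_like(z)
        for j, region in enumerate(scheme.regions):
            counts[:, j] = _lognormal_margin(
                z[:, j], float(g.region_means[region]), float(g.region_cv[region])
            )
        counts = np.maximum(counts, 0.0)
        for i in range(g.n_animals):
            rows.append({"group": g.name, **dict(zip(scheme.regions, counts[i]))})
            index.append(f"{g.name}_{i + 1:02d}")
    frame = pd.DataFrame(rows, index=pd.Index(index, name="animal_id"))
    return CountTable(scheme=scheme, frame=frame, normalized=False)


def paperlike_config(n_animals: int = 8, seed: int = 0) -> SyntheticConfig:
    """Default three-group fixture: 3 groups x n_animals x 12 regions.

    NS-like: near-independent regions (identity plus weak shared noise);
    2S-like: strong global coordination (r ~ 0.7 everywhere);
    10S-like: an amygdala-only block (r ~ 0.8), weak elsewhere.
    """
    scheme = default_scheme()
    base_means = {
        "DG": 60.0, "CA3": 45.0, "CA1": 80.0, "BLA": 70.0, "CeA": 50.0,
        "RSC": 120.0, "IL": 55.0, "PL": 65.0, "Cg1": 90.0, "Cg2": 75.0,
        "Re": 40.0, "PV": 35.0,
    }
    cv = {r: 0.35 for r in scheme.regions}

    def scaled(factors: Mapping[str, float]) -> dict[str, float]:
        return {r: base_means[r] * factors.get(r, 1.0) for r in scheme.regions}

    ns = GroupSpec(
        name="NS",
        n_animals=n_animals,
        region_means=dict(base_means),
        region_cv=dict(cv),
        latent_correlation=block_correlation(scheme, 0.05, 0.05, [list(scheme.regions)]),
    )
    two_s = GroupSpec(
        name="2S",
        n_animals=n_animals,
        region_means=scaled({"BLA": 1.6, "CeA": 1.5, "PV": 1.7, "Re": 1.4, "RSC": 1.3}),
        region_cv=dict(cv),
        latent_correlation=block_correlation(scheme, 0.7, 0.7, [list(scheme.regions)]),
    )
    ten_s = GroupSpec(
        name="10S",
        n_animals=n_animals,
        region_means=scaled({"BLA": 2.0, "CeA": 2.2, "PV": 2.4, "IL": 0.7}),
        region_cv=dict(cv),
        latent_correlation=block_correlation(scheme, 0.8, 0.05, [["BLA", "CeA"]]),
    )
    return SyntheticConfig(scheme=scheme, groups=(ns, two_s, ten_s), seed=seed)


PRESETS = {"paperlike": paperlike_config}
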