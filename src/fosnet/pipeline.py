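"""End-to-end orchestration: counts -> matrices -> networks -> metrics -> report.

Every stage's artifact is written to the output directory (matrices and
metric tables as CSV, networks as edge lists and GraphML, the full report as
JSON). Given the same inputs and seed the run is fully reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .communities import leading_eigenvector
from .connectivity import (
    compare_group_r,
    correlation_matrix,
    offdiagonal_values,
    pair_labels,
)
from .counts import normalize_to_control, read_counts, write_counts
from .errors import FosnetError
from .metrics import COMPARABLE_METRICS, compare_group_metrics, metric_table
from .networks import build_network, compute_threshold
from .scheme import RegionScheme, default_scheme
from .smallworld import smallworld_comparison

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Run parameters for :func:`run_full_analysis`."""

    control_group: str = "NS"
    replicates: int = 1000
    seed: int = 0
    normalize: bool = True
    collection_rule: str = "incident"
    clustering_iterations: int = 1000
    alpha: float = 0.05
    force: bool = False


def _write_r_values(m, path) -> None:
    labels = pair_labels(m.regions)
    frame = pd.DataFrame(
        {
            "region_a": [a for a, _ in labels],
            "region_b": [b for _, b in labels],
            "r": offdiagonal_values(m),
        }
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def run_full_analysis(
    counts_path,
    scheme_path=None,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the whole analysis and write all artifacts under ``out_dir``.

    Returns the report dictionary (also written to report.json).
    """
    config = config or AnalysisConfig()
    if out_dir is None:
        raise FosnetError("an output directory is required")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FosnetError(
            f"output directory {out} exists and is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)

    scheme = (
        RegionScheme.from_yaml(scheme_path) if scheme_path is not None else default_scheme()
    )
    table = read_counts(counts_path, scheme)
    if config.control_group not in table.groups:
        raise FosnetError(f"control group {config.control_group!r} not present")
    if config.normalize:
        table = normalize_to_control(table, config.control_group)
        write_counts(table, out / "counts_normalized.csv")

    groups = list(table.groups)
    report: dict = {
        "fosnet_version": __version__,
        "config": {
            "control_group": config.control_group,
            "replicates": config.replicates,
            "seed": config.seed,
            "normalize": config.normalize,
            "collection_rule": config.collection_rule,
            "clustering_iterations": config.clustering_iterations,
        },
        "scheme": {
            "regions": list(scheme.regions),
            "collections": {k: list(v) for k, v in scheme.collections.items()},
        },
        "groups": groups,
    }

    # --- correlation stage -------------------------------------------------
    matrices = [correlation_matrix(table, g) for g in groups]
    for m in matrices:
        m.to_frame().to_csv(out / f"correlation_{m.group}.csv", float_format="%.10g")
        _write_r_values(m, out / f"r_values_{m.group}.csv")
    report["correlation"] = {
        "mean_r": {m.group: float(offdiagonal_values(m).mean()) for m in matrices},
        "comparisons": {},
    }
    report["correlation"]["comparisons"]["all"] = compare_group_r(
        matrices, scheme, "all", alpha=config.alpha
    ).to_dict()
    for name in scheme.collections:
        report["correlation"]["comparisons"][name] = compare_group_r(
            matrices, scheme, name, rule=config.collection_rule, alpha=config.alpha
        ).to_dict()

    # --- network construction ---------------------------------------------
    threshold = compute_threshold(matrices)
    report["threshold"] = threshold
    nets = [build_network(m, threshold) for m in matrices]
    report["networks"] = {}
    for net in nets:
        net.write_edge_list(out / f"edges_{net.group}.csv")
        net.write_graphml(out / f"network_{net.group}.graphml")
        report["networks"][net.group] = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "mean_degree": 2.0 * net.n_edges / net.n_nodes,
        }

    # --- metrics ------------------------------------------------------------
    tables = [metric_table(net) for net in nets]
    report["metrics"] = {"per_group": {}, "comparisons": {}}
    for t in tables:
        t.write_csv(out / f"metrics_{t.network}.csv")
        report["metrics"]["per_group"][t.network] = {
            "global_efficiency": t.global_efficiency,
            "clustering_coefficient": t.clustering_coefficient,
        }
    for metric in COMPARABLE_METRICS:
        report["metrics"]["comparisons"][metric] = compare_group_metrics(
            tables, metric, alpha=config.alpha
        ).to_dict()

    # --- small-world null comparison ----------------------------------------
    report["smallworld"] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(len(nets))
    for net, seed in zip(nets, seeds):
        if net.n_edges == 0:
            report["smallworld"][net.group] = {
                "error": "edgeless network; comparison undefined"
            }
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = smallworld_comparison(
                net,
                replicates=config.replicates,
                seed=seed,
                clustering_iterations=config.clustering_iterations,
            )
        report["smallworld"][net.group] = comp.to_dict()
        pd.DataFrame(
            {"replicate_efficiency": comp.replicate_efficiencies}
        ).to_csv(out / f"smallworld_replicates_{net.group}.csv", index=False,
                 float_format="%.10g")

    # --- communities ---------------------------------------------------------
    report["communities"] = {}
    for net in nets:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = leading_eigenvector(net)
        report["communities"][net.group] = part.to_dict()
        pd.DataFrame(
            {"region": list(part.membership), "community": list(part.membership.values())}
        ).to_csv(out / f"communities_{net.group}.csv", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
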