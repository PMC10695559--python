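"""Centrality and efficiency metrics with the pipeline's path conventions.

Two distinct path definitions coexist deliberately: betweenness uses
unweighted geodesics (shortest = fewest edges, fractional credit across tied
geodesics), while nodal/global efficiency uses weighted shortest paths with
edge length 1/r. Disconnected pairs contribute exactly 0 to efficiency.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import DomainError, FosnetError
from .networks import FunctionalNetwork
from .stats import _rank_average

__all__ = [
    "MetricTable",
    "degree",
    "betweenness",
    "weighted_distances",
    "nodal_efficiency",
    "global_efficiency",
    "clustering_coefficient",
    "metric_table",
    "compare_group_metrics",
]

COMPARABLE_METRICS = ("degree", "betweenness", "nodal_efficiency")


def _node_index(net: FunctionalNetwork, node: str) -> int:
    try:
        return net.nodes.index(node)
    except ValueError:
        raise KeyError(f"unknown node {node!r}") from None


def degree(net: FunctionalNetwork, node: str | None = None):
    """Number of incident edges, for one node or all nodes (in node order)."""
    adj = net.adjacency()
    degrees = adj.sum(axis=1).astype(int)
    if node is None:
        return degrees
    return int(degrees[_node_index(net, node)])


def _betweenness_all(adj: np.ndarray) -> np.ndarray:
    """Brandes accumulation on unweighted geodesics, unordered pairs, unnormalized."""
    n = adj.shape[0]
    neighbors = [np.flatnonzero(adj[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair visited from both endpoints


def betweenness(net: FunctionalNetwork, node: str | None = None):
    """Fractional geodesic betweenness; unnormalized; unweighted paths."""
    bc = _betweenness_all(net.adjacency())
    if node is None:
        return bc
    return float(bc[_node_index(net, node)])


def weighted_distances(net: FunctionalNetwork) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/r; inf if disconnected."""
    if any(weight <= 0 for _, _, weight in net.edges):
        raise DomainError("non-positive edge weight; 1/r distance undefined")
    w = net.weight_matrix()
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def nodal_efficiency(net: FunctionalNetwork, node: str | None = None):
    """Mean of 1/d(node, other) over all other nodes; 1/inf counts as 0."""
    d = weighted_distances(net)
    n = d.shape[0]
    if n < 2:
        raise FosnetError("need at least two nodes")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    if node is None:
        return eff
    return float(eff[_node_index(net, node)])


def global_efficiency(net: FunctionalNetwork) -> float:
    """Arithmetic mean of the nodal efficiencies."""
    return float(np.mean(nodal_efficiency(net)))


def _local_clustering(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return c


def _weighted_local_clustering(w: np.ndarray) -> np.ndarray:
    """Geometric-mean (Onnela) weighted variant, weights scaled by max."""
    if w.max() <= 0:
        return np.zeros(w.shape[0])
    wn = np.cbrt(w / w.max())
    deg = (w > 0).sum(axis=1)
    cyc = np.diag(wn @ wn @ wn)
    possible = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, cyc / possible, 0.0)
    return c


def clustering_coefficient(net: FunctionalNetwork, weighted: bool = False) -> float:
    """Average local clustering coefficient; degree<2 nodes contribute 0.

    The unweighted coefficient is the default (it is the statistic matched by
    the lattice-rewiring null model); ``weighted=True`` selects the
    geometric-mean variant.
    """
    if net.n_nodes < 3:
        raise FosnetError("need at least three nodes")
    if weighted:
        return float(np.mean(_weighted_local_clustering(net.weight_matrix())))
    return float(np.mean(_local_clustering(net.adjacency())))


@dataclass(frozen=True)
class MetricTable:
    """Per-node metrics with descending average-ranked columns, plus network summaries."""

    network: str
    frame: pd.DataFrame  # index: node; columns: metric + rank_<metric>
    global_efficiency: float
    clustering_coefficient: float

    def values(self, metric: str) -> np.ndarray:
        if metric not in COMPARABLE_METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        return self.frame[metric].to_numpy()

    def write_csv(self, path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "node"})
        out.to_csv(path, index=False, float_format="%.10g")


def _descending_average_rank(values: np.ndarray) -> np.ndarray:
    return len(values) + 1 - _rank_average(np.asarray(values, dtype=float))


def metric_table(net: FunctionalNetwork) -> MetricTable:
    deg = degree(net)
    bc = betweenness(net)
    eff = nodal_efficiency(net)
    frame = pd.DataFrame(
        {
            "degree": deg,
            "betweenness": bc,
            "nodal_efficiency": eff,
        },
        index=list(net.nodes),
    )
    for metric in COMPARABLE_METRICS:
        frame[f"rank_{metric}"] = _descending_average_rank(frame[metric].to_numpy())
    return MetricTable(
        network=net.group,
        frame=frame,
        global_efficiency=float(np.mean(eff)),
        clustering_coefficient=clustering_coefficient(net),
    )


def compare_group_metrics(tables: Sequence[MetricTable], metric: str, alpha: float = 0.05):
    """Kruskal-Wallis + pairwise Mann-Whitney over the per-node metric values."""
    from .connectivity import _compare_samples

    if len(tables) < 2:
        raise FosnetError("need at least two metric tables")
    samples = [t.values(metric) for t in tables]
    labels = [t.network for t in tables]
    return _compare_samples(labels, samples, alpha=alpha)
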