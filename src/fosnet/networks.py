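"""Threshold derivation and construction of weighted functional networks.

A single cutoff — the mean plus one sample SD of the pooled off-diagonal r
values across all groups — is applied to every group's matrix. Edges retain
their signed r as weight; only r strictly above the threshold survive, so
negative correlations are never retained. Isolated nodes stay in the graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import CorrelationMatrix, offdiagonal_values
from .errors import FosnetError, UndefinedSDError

__all__ = ["FunctionalNetwork", "compute_threshold", "build_network"]


@dataclass(frozen=True)
class FunctionalNetwork:
    """Thresholded weighted undirected graph over a fixed region node set.

    Edges are stored as (a, b, weight) with a before b in node order; no
    self-loops, no duplicates; every weight strictly exceeds the threshold.
    """

    group: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        index = {n: i for i, n in enumerate(self.nodes)}
        canon = []
        seen = set()
        for a, b, w in self.edges:
            if a not in index or b not in index:
                raise FosnetError(f"edge endpoint not in node set: ({a!r}, {b!r})")
            if a == b:
                raise FosnetError(f"self-loop on {a!r}")
            if index[a] > index[b]:
                a, b = b, a
            if (a, b) in seen:
                raise FosnetError(f"duplicate edge ({a!r}, {b!r})")
            seen.add((a, b))
            if not w > self.threshold:
                raise FosnetError(
                    f"edge ({a!r}, {b!r}) weight {w} does not exceed threshold "
                    f"{self.threshold}"
                )
            canon.append((a, b, float(w)))
        canon.sort(key=lambda e: (index[e[0]], index[e[1]]))
        object.__setattr__(self, "edges", tuple(canon))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric weight matrix; 0 where no edge."""
        index = {n: i for i, n in enumerate(self.nodes)}
        w = np.zeros((self.n_nodes, self.n_nodes))
        for a, b, weight in self.edges:
            w[index[a], index[b]] = weight
            w[index[b], index[a]] = weight
        return w

    def adjacency(self) -> np.ndarray:
        return self.weight_matrix() != 0

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["region_a", "region_b", "r"])

    def write_edge_list(self, path) -> None:
        self.to_edge_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_edge_list(
        cls, path, nodes: Sequence[str], threshold: float, group: str = ""
    ) -> "FunctionalNetwork":
        frame = pd.read_csv(path)
        edges = [
            (str(r.region_a), str(r.region_b), float(r.r))
            for r in frame.itertuples(index=False)
        ]
        return cls(group=group, nodes=tuple(nodes), edges=tuple(edges), threshold=threshold)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(group=self.group, threshold=self.threshold)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def compute_threshold(matrices: Sequence[CorrelationMatrix]) -> float:
    """Mean + 1 sample SD (ddof=1) of the pooled upper-triangle r values."""
    if len(matrices) == 0:
        raise FosnetError("need at least one matrix")
    pooled = np.concatenate([offdiagonal_values(m) for m in matrices])
    if len(pooled) < 2:
        raise UndefinedSDError("fewer than two pooled r values; SD undefined")
    return float(pooled.mean() + pooled.std(ddof=1))


def build_network(m: CorrelationMatrix, threshold: float) -> FunctionalNetwork:
    """Keep edges with r strictly above the threshold; isolated nodes remain."""
    edges = []
    p = len(m.regions)
    for i in range(p):
        for j in range(i + 1, p):
            if m.r[i, j] > threshold:
                edges.append((m.regions[i], m.regions[j], float(m.r[i, j])))
    return FunctionalNetwork(
        group=m.group, nodes=m.regions, edges=tuple(edges), threshold=threshold
    )
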