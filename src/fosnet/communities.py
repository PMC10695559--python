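"""Leading-eigenvector community detection on weighted functional networks.

Recursive spectral bisection of the modularity matrix: each group is split by
the sign pattern of the leading eigenvector of its generalized modularity
submatrix, stopping when the leading eigenvalue is non-positive or the split
does not increase Q. No refinement pass is applied, keeping the procedure
deterministic (eigenvector sign is fixed by making its largest-magnitude
entry positive). Isolated nodes form singleton communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import FosnetError, UndefinedModularityError
from .networks import FunctionalNetwork

__all__ = ["Partition", "modularity", "leading_eigenvector"]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to a community, with the partition's modularity."""

    network: str
    membership: Mapping[str, int]
    n_communities: int
    modularity: float

    def __post_init__(self) -> None:
        labels = sorted(set(self.membership.values()))
        if labels != list(range(len(labels))):
            raise FosnetError("community indices must be contiguous from 0")
        if len(labels) != self.n_communities:
            raise FosnetError("n_communities does not match membership")

    def communities(self) -> list[tuple[str, ...]]:
        out: list[list[str]] = [[] for _ in range(self.n_communities)]
        for node, c in self.membership.items():
            out[c].append(node)
        return [tuple(c) for c in out]

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "membership": dict(self.membership),
            "n_communities": self.n_communities,
            "modularity": self.modularity,
        }


def modularity(net: FunctionalNetwork, membership: Mapping[str, int]) -> float:
    """Weighted Newman modularity Q of a given node-to-community assignment."""
    missing = [n for n in net.nodes if n not in membership]
    if missing:
        raise FosnetError(f"nodes without community assignment: {missing}")
    w = net.weight_matrix()
    two_m = w.sum()
    if two_m == 0:
        raise UndefinedModularityError("modularity undefined for an edgeless network")
    k = w.sum(axis=1)
    labels = np.array([membership[n] for n in net.nodes])
    same = labels[:, None] == labels[None, :]
    b = w - np.outer(k, k) / two_m
    return float((b * same).sum() / two_m)


def _relabel(nodes: tuple[str, ...], groups: list[list[int]]) -> dict[str, int]:
    """Contiguous community indices, ordered by each community's first node."""
    groups = sorted(groups, key=min)
    membership: dict[str, int] = {}
    for idx, members in enumerate(groups):
        for i in members:
            membership[nodes[i]] = idx
    return membership


def leading_eigenvector(net: FunctionalNetwork) -> Partition:
    """Recursive leading-eigenvector partition of a weighted network."""
    nodes = net.nodes
    w = net.weight_matrix()
    two_m = w.sum()
    if two_m == 0:
        warnings.warn("edgeless network: singleton communities, Q reported as 0")
        membership = {n: i for i, n in enumerate(nodes)}
        return Partition(
            network=net.group,
            membership=membership,
            n_communities=len(nodes),
            modularity=0.0,
        )
    k = w.sum(axis=1)
    b = w - np.outer(k, k) / two_m

    def q_of(groups: list[list[int]]) -> float:
        total = 0.0
        for members in groups:
            idx = np.ix_(members, members)
            total += b[idx].sum()
        return total / two_m

    final: list[list[int]] = []
    # isolated nodes are split off up front as singletons
    isolated = [i for i in range(len(nodes)) if k[i] == 0]
    for i in isolated:
        final.append([i])
    pending: list[list[int]] = []
    connected = [i for i in range(len(nodes)) if k[i] > 0]
    if connected:
        pending.append(connected)

    while pending:
        group = pending.pop()
        if len(group) == 1:
            final.append(group)
            continue
        idx = np.ix_(group, group)
        bg = b[idx].copy()
        bg -= np.diag(bg.sum(axis=1))  # generalized modularity matrix for subgraphs
        eigvals, eigvecs = np.linalg.eigh(bg)
        lead = eigvecs[:, -1]
        if eigvals[-1] <= _EIG_TOL:
            final.append(group)
            continue
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        left = [g for g, v in zip(group, lead) if v > 0]
        right = [g for g, v in zip(group, lead) if v <= 0]
        if not left or not right:
            final.append(group)
            continue
        q_before = q_of([*final, *pending, group])
        q_after = q_of([*final, *pending, left, right])
        if q_after <= q_before + 1e-12:
            final.append(group)
            continue
        pending.append(left)
        pending.append(right)

    membership = _relabel(nodes, final)
    return Partition(
        network=net.group,
        membership=membership,
        n_communities=len(final),
        modularity=modularity(net, membership),
    )
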