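"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive — exhaustive enumeration and repeated
edge relaxation — and shares no code with the package implementations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def relaxation_distances(nodes, edges, lengths=None):
    """All-pairs shortest paths by iterating edge relaxation n times.

    ``edges`` is a list of (a, b, w); ``lengths`` maps weight -> edge length
    (defaults to 1/w). Returns a dict-of-dict distance table with inf for
    unreachable pairs.
    """
    if lengths is None:
        lengths = lambda w: 1.0 / w  # noqa: E731
    d = {a: {b: np.inf for b in nodes} for a in nodes}
    for a in nodes:
        d[a][a] = 0.0
    for _ in range(len(nodes)):
        for a, b, w in edges:
            ell = lengths(w)
            for s in nodes:
                if d[s][a] + ell < d[s][b]:
                    d[s][b] = d[s][a] + ell
                if d[s][b] + ell < d[s][a]:
                    d[s][a] = d[s][b] + ell
    return d


def enumerate_geodesics(adjacency, s, t):
    """All unweighted shortest paths from s to t, as node tuples."""
    n = len(adjacency)
    dist = [None] * n
    dist[s] = 0
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in range(n):
            if adjacency[v][w] and dist[w] is None:
                dist[w] = dist[v] + 1
                queue.append(w)
    if dist[t] is None:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(tuple(path))
            return
        for w in range(n):
            if adjacency[v][w] and dist[w] == dist[v] + 1:
                extend(path + [w])

    extend([s])
    return paths


def betweenness_by_enumeration(adjacency):
    """Fractional betweenness by explicitly listing every geodesic."""
    n = len(adjacency)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_geodesics(adjacency, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def efficiency_from_distances(d, nodes):
    """Nodal and global efficiency from a dict-of-dict distance table."""
    nodal = {}
    for a in nodes:
        inv = [1.0 / d[a][b] if np.isfinite(d[a][b]) else 0.0 for b in nodes if b != a]
        nodal[a] = float(np.mean(inv))
    return nodal, float(np.mean(list(nodal.values())))


def best_two_partition(nodes, weight, q_func):
    """Exhaustive search over all 2-partitions; returns (best_q, best_split)."""
    nodes = list(nodes)
    best_q, best = -np.inf, None
    first = nodes[0]
    rest = nodes[1:]
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            left = {first, *combo}
            membership = {v: (0 if v in left else 1) for v in nodes}
            q = q_func(membership)
            if q > best_q:
                best_q, best = q, membership
    return best_q, best
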