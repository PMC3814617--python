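"""Markov Cluster algorithm, from scratch.

Flow simulation on the co-evolution network: alternate expansion (matrix
squaring) and inflation (entrywise power followed by column renormalization)
until the flow matrix stops changing.  Inflation strengthens strong flows at
the expense of weak ones, so flow condenses onto attractor nodes; clusters
are read off as the attractor basins.  Dense numpy arithmetic -- networks at
the per-organism scale this tool targets stay in the hundreds of nodes.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import networkx as nx
import numpy as np

DEFAULT_INFLATION = 2.0
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-8
DEFAULT_PRUNE_CUTOFF = 1e-5

ClusterPartition = list[set]


def _edge_weight(data: dict) -> float:
    return float(data.get("C", data.get("weight", 1.0)))


def build_transition_matrix(
    network: nx.Graph, self_loop_weight: float | None = None
) -> tuple[np.ndarray, list]:
    """Column-stochastic flow matrix of the network, plus the node ordering.

    Self-loops are added before normalization; by default each node's loop
    weight is its maximum incident edge weight (1.0 for isolated nodes),
    which damps the parity oscillations of odd-length paths.  Edge weights
    must be non-negative.
    """
    nodes = sorted(network.nodes)
    n = len(nodes)
    if n == 0:
        return np.zeros((0, 0)), []
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in network.edges(data=True):
        w = _edge_weight(data)
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = w
    if self_loop_weight is None:
        loops = np.where(m.max(axis=0) > 0, m.max(axis=0), 1.0)
    else:
        loops = np.full(n, float(self_loop_weight))
    m[np.diag_indices(n)] = loops
    return m / m.sum(axis=0, keepdims=True), nodes


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0, keepdims=True)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_cluster(
    matrix: np.ndarray,
    nodes: Sequence | None = None,
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    prune_cutoff: float = DEFAULT_PRUNE_CUTOFF,
    on_iteration=None,
) -> ClusterPartition:
    """Cluster a column-stochastic matrix; returns disjoint node sets.

    ``on_iteration``, when given, is called with the matrix after every
    inflation step (diagnostics: convergence traces, invariant checks).

    Iterates expansion and inflation with pruning of entries below
    ``prune_cutoff`` until the largest entry change drops under ``tol`` or
    ``max_iter`` is reached (then a warning is emitted and the current state
    is interpreted).  Attractors are the nodes retaining flow on the
    diagonal; every node joins the attractor holding the most of its flow,
    with lexicographic node id breaking exact ties.  Deterministic: no
    randomness anywhere.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if n == 0:
        return []
    if nodes is None:
        nodes = list(range(n))
    if m.shape != (n, n) or (m < 0).any() or not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("input matrix is not column-stochastic")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")

    for _ in range(max_iter):
        expanded = m @ m
        inflated = _normalize_columns(expanded**inflation)
        inflated[inflated < prune_cutoff] = 0.0
        inflated = _normalize_columns(inflated)
        if on_iteration is not None:
            on_iteration(inflated)
        change = np.abs(inflated - m).max()
        m = inflated
        if change < tol:
            break
    else:
        warnings.warn("MCL did not converge within max_iter; clustering current state")

    return _interpret(m, list(nodes))


def _interpret(m: np.ndarray, nodes: list) -> ClusterPartition:
    """Read clusters off the limit matrix (attractor basins)."""
    n = len(nodes)
    diag = np.diag(m)
    attractors = np.flatnonzero(diag > 0)
    if attractors.size == 0:  # degenerate; every node on its own
        return [{nodes[i]} for i in range(n)]

    # attractor systems: attractors sharing flow belong to one cluster seed
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    att_set = set(attractors.tolist())
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > 0 or m[j, i] > 0):
                union(i, j)

    assignment: dict[int, int] = {}
    for j in range(n):
        if j in att_set:
            assignment[j] = find(j)
            continue
        mass = m[attractors, j]
        if mass.max() <= 0:
            assignment[j] = -j - 1  # unattracted node: own singleton
            continue
        best = mass.max()
        tied = attractors[mass >= best - 0.0]
        target = min(tied, key=lambda i: str(nodes[i]))
        assignment[j] = find(target)

    clusters: dict[int, set] = {}
    for j, root in assignment.items():
        clusters.setdefault(root, set()).add(nodes[j])
    return sorted(clusters.values(), key=lambda c: (-len(c), sorted(map(str, c))))


def cluster_network(
    network: nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    prune_cutoff: float = DEFAULT_PRUNE_CUTOFF,
) -> ClusterPartition:
    """MCL partition of a weighted network (singletons included)."""
    matrix, nodes = build_transition_matrix(network)
    return mcl_cluster(matrix, nodes, inflation, max_iter, tol, prune_cutoff)


def sweep_thresholds(
    network: nx.Graph,
    thresholds: Sequence[float],
    query_gene=None,
    inflation: float = DEFAULT_INFLATION,
) -> list[dict]:
    """Re-threshold, re-cluster and track one gene's cluster size.

    ``network`` carries all scored edges; at each threshold only edges with
    C strictly above it survive (nodes are kept).  Returns one record per
    threshold with the partition and, when ``query_gene`` is given, the size
    of its cluster (0 if the gene is not a network node).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    out = []
    for t in thresholds:
        sub = nx.Graph()
        sub.add_nodes_from(network.nodes)
        for u, v, data in network.edges(data=True):
            if _edge_weight(data) > t:
                sub.add_edge(u, v, **data)
        partition = cluster_network(sub, inflation=inflation)
        record = {"threshold": t, "partition": partition}
        if query_gene is not None:
            size = 0
            if query_gene in sub:
                for c in partition:
                    if query_gene in c:
                        size = len(c)
                        break
            record["query_cluster_size"] = size
        out.append(record)
    return out
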