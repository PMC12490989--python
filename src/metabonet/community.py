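"""Louvain community detection and modularity.

Modularity of a partition C on a weighted undirected graph:

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j)

with A the weight matrix, k_i the weighted degree and m the total edge
weight.  By default edges enter with the absolute value of their signed
partial-correlation weight (``weights_mode="absolute"``); ``"binary"``
uses unit weights.  The Louvain heuristic greedily moves nodes between
communities and aggregates, which is not deterministic by nature, so the
implementation fixes a seeded visiting order: results are reproducible
given (seed, node order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UndefinedMetricError
from .graph import SimpleGraph

WEIGHTS_MODES = ("absolute", "binary")


@dataclass(frozen=True)
class CommunityPartition:
    """Node -> community assignment with its modularity score."""

    assignment: dict
    modularity_q: float
    seed: int = 0
    weights_mode: str = "absolute"

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if labels != list(range(len(labels))):
            raise ConfigurationError("community labels must be contiguous integers from 0")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def __getitem__(self, node):
        return self.assignment[node]


def _edge_weight(w: float, weights_mode: str) -> float:
    if weights_mode == "absolute":
        return abs(w)
    if weights_mode == "binary":
        return 1.0
    raise ConfigurationError(
        f"unknown weights mode {weights_mode!r}; expected one of {WEIGHTS_MODES}"
    )


def modularity(graph: SimpleGraph, assignment: dict, weights_mode: str = "absolute") -> float:
    """Newman modularity Q of a given node partition."""
    m = 0.0
    k = {u: 0.0 for u in graph.nodes}
    for u, v, w in graph.edge_list():
        w = _edge_weight(w, weights_mode)
        m += w
        k[u] += w
        k[v] += w
    if m == 0:
        return 0.0
    q = 0.0
    for u, v, w in graph.edge_list():
        if assignment[u] == assignment[v]:
            q += _edge_weight(w, weights_mode)
    q /= m  # = (1/2m) * sum over ordered pairs of A_ij inside communities
    for u in graph.nodes:
        for v in graph.nodes:
            if assignment[u] == assignment[v]:
                q -= k[u] * k[v] / (4.0 * m * m)
    return q


def louvain_communities(
    graph: SimpleGraph,
    weights_mode: str = "absolute",
    seed: int = 0,
    resolution: float = 1.0,
) -> CommunityPartition:
    """Greedy Louvain modularity optimisation.

    Requires at least one edge.  Deterministic for a fixed seed and node
    order; community labels are contiguous integers assigned in order of
    first appearance along the node order.
    """
    if graph.m == 0:
        raise UndefinedMetricError("community detection requires at least one edge")
    rng = np.random.default_rng(seed)
    n = graph.n
    # working multigraph: adjacency dicts + self-loop weights
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    loops = [0.0] * n
    for u, v, w in graph.edge_list():
        i, j = graph.index(u), graph.index(v)
        w = _edge_weight(w, weights_mode)
        adj[i][j] = adj[i].get(j, 0.0) + w
        adj[j][i] = adj[j].get(i, 0.0) + w
    membership = list(range(n))  # original node -> current community id

    while True:
        node2com, improved = _one_level(adj, loops, rng, resolution)
        membership = [node2com[c] for c in membership]
        n_com = len(set(node2com))
        if not improved or n_com == len(adj):
            break
        adj, loops = _aggregate(adj, loops, node2com, n_com)

    # contiguous labels in order of first appearance along node order
    relabel: dict[int, int] = {}
    assignment = {}
    for node, com in zip(graph.nodes, membership):
        if com not in relabel:
            relabel[com] = len(relabel)
        assignment[node] = relabel[com]
    q = modularity(graph, assignment, weights_mode=weights_mode)
    return CommunityPartition(assignment, q, seed=seed, weights_mode=weights_mode)


def _one_level(adj, loops, rng, resolution):
    """One pass of local moving; returns (node -> contiguous community, improved)."""
    n = len(adj)
    degree = [sum(adj[i].values()) + 2.0 * loops[i] for i in range(n)]
    two_m = sum(degree)
    node2com = list(range(n))
    sum_tot = degree[:]  # total degree per community
    improved = False
    if two_m == 0:
        return node2com, False
    order = list(rng.permutation(n))
    moved = True
    while moved:
        moved = False
        for i in order:
            com_i = node2com[i]
            # weights from i to neighbouring communities
            neigh: dict[int, float] = {}
            for j, w in adj[i].items():
                neigh[node2com[j]] = neigh.get(node2com[j], 0.0) + w
            # remove i from its community
            sum_tot[com_i] -= degree[i]
            best_com, best_gain = com_i, neigh.get(com_i, 0.0) - resolution * sum_tot[com_i] * degree[i] / two_m
            for com in sorted(neigh):
                gain = neigh[com] - resolution * sum_tot[com] * degree[i] / two_m
                if gain > best_gain + 1e-12:
                    best_gain, best_com = gain, com
            sum_tot[best_com] += degree[i]
            if best_com != com_i:
                node2com[i] = best_com
                moved = True
                improved = True
    # renumber communities contiguously
    relabel: dict[int, int] = {}
    for i in range(n):
        com = node2com[i]
        if com not in relabel:
            relabel[com] = len(relabel)
        node2com[i] = relabel[com]
    return node2com, improved


def _aggregate(adj, loops, node2com, n_com):
    """Collapse communities into super-nodes."""
    new_adj: list[dict[int, float]] = [dict() for _ in range(n_com)]
    new_loops = [0.0] * n_com
    for i in range(len(adj)):
        ci = node2com[i]
        new_loops[ci] += loops[i]
        for j, w in adj[i].items():
            if j < i:
                continue
            cj = node2com[j]
            if ci == cj:
                new_loops[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, new_loops
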