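"""Graph container and node-level / global network statistics.

All distance-based statistics (closeness, harmonic closeness,
betweenness, diameter, average path length) use **unweighted** hop-count
distances on the binary adjacency; the signed partial-correlation weights
are retained on the edges for sign rendering, export and community
detection only.  Normalisation conventions:

* closeness: (number of reachable nodes) / (sum of distances to them) —
  (n-1)/sum(d) on connected graphs, 0 for isolated nodes;
* harmonic closeness: mean of reciprocal distances over the other n-1
  nodes, with 1/inf = 0 for unreachable pairs;
* betweenness: Brandes accumulation, unnormalised pair counts with
  fractional credit over equally short paths, endpoints excluded;
* eigenvector centrality: leading eigenvector of the binary adjacency,
  scaled so the top node scores exactly 1;
* HITS authority/hub: on an undirected graph both equal the leading
  eigenvector direction, reported with unit Euclidean norm.

These conventions reproduce the scales used by common network GUIs
(closeness a ratio of integers, betweenness on the raw pair-count scale,
one node at eigenvector 1.0, authority ~= hub).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MetabonetError, UndefinedMetricError

CENTRALITY_METRICS = (
    "closeness", "harmonic_closeness", "betweenness", "authority", "hub",
    "clustering_coefficient", "triangles", "eigenvector",
)


class SimpleGraph:
    """Undirected simple graph with signed edge weights.

    Parameters
    ----------
    nodes : ordered node identifiers.
    edges : iterable of ``(u, v)`` or ``(u, v, weight)``; default weight 1.
    """

    def __init__(self, nodes, edges=()):
        self.nodes: tuple = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise MetabonetError("duplicate node identifiers")
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self.weights: dict[tuple, float] = {}
        self.adj: dict = {n: [] for n in self.nodes}
        for edge in edges:
            u, v, w = edge if len(edge) == 3 else (*edge, 1.0)
            self.add_edge(u, v, w)

    def add_edge(self, u, v, weight: float = 1.0) -> None:
        if u == v:
            raise MetabonetError(f"self-loop on node {u!r}")
        for x in (u, v):
            if x not in self._index:
                raise MetabonetError(f"unknown node {x!r}")
        key = self._key(u, v)
        if key in self.weights:
            raise MetabonetError(f"duplicate edge {u!r}-{v!r}")
        self.weights[key] = float(weight)
        self.adj[u].append(v)
        self.adj[v].append(u)

    def _key(self, u, v):
        return (u, v) if self._index[u] < self._index[v] else (v, u)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.weights)

    def degree(self, node) -> int:
        return len(self.adj[node])

    def has_edge(self, u, v) -> bool:
        return self._key(u, v) in self.weights

    def weight(self, u, v) -> float:
        return self.weights[self._key(u, v)]

    def edge_list(self) -> list[tuple]:
        """Edges as (u, v, weight), u before v in node order."""
        return [(u, v, w) for (u, v), w in self.weights.items()]

    def index(self, node) -> int:
        return self._index[node]

    def adjacency_matrix(self, weighted: bool = False) -> np.ndarray:
        a = np.zeros((self.n, self.n))
        for (u, v), w in self.weights.items():
            i, j = self._index[u], self._index[v]
            a[i, j] = a[j, i] = w if weighted else 1.0
        return a


# ---------------------------------------------------------------------------
# distances

def shortest_path_distances(graph: SimpleGraph) -> np.ndarray:
    """All-pairs hop-count distances by BFS; inf for unreachable pairs."""
    n = graph.n
    dist = np.full((n, n), np.inf)
    for s, source in enumerate(graph.nodes):
        dist[s, s] = 0.0
        frontier = [source]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in graph.adj[u]:
                    j = graph.index(v)
                    if not np.isfinite(dist[s, j]):
                        dist[s, j] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def closeness_centrality(graph: SimpleGraph, node=None):
    """Closeness = reachable count / sum of distances to reachable nodes."""
    dist = shortest_path_distances(graph)
    values = {}
    for i, u in enumerate(graph.nodes):
        row = dist[i]
        reach = np.isfinite(row) & (row > 0)
        total = row[reach].sum()
        values[u] = float(reach.sum() / total) if total > 0 else 0.0
    return values if node is None else values[node]


def harmonic_closeness(graph: SimpleGraph, node=None):
    """Mean reciprocal distance over the other n-1 nodes (1/inf = 0)."""
    dist = shortest_path_distances(graph)
    n = graph.n
    values = {}
    for i, u in enumerate(graph.nodes):
        row = dist[i]
        finite = np.isfinite(row) & (row > 0)
        s = float(np.sum(1.0 / row[finite]))
        values[u] = s / (n - 1) if n > 1 else 0.0
    return values if node is None else values[node]


def betweenness_centrality(graph: SimpleGraph) -> dict:
    """Brandes betweenness, unnormalised, endpoints excluded.

    Each unordered pair contributes total credit 1, split fractionally
    across its equally short paths.
    """
    bc = {v: 0.0 for v in graph.nodes}
    for s in graph.nodes:
        # single-source shortest-path DAG
        stack = []
        pred: dict = {v: [] for v in graph.nodes}
        sigma = {v: 0.0 for v in graph.nodes}
        dist = {v: -1 for v in graph.nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            u = queue[head]
            head += 1
            stack.append(u)
            for v in graph.adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
        delta = {v: 0.0 for v in graph.nodes}
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # undirected: each pair was counted from both endpoints
    return {v: val / 2.0 for v, val in bc.items()}


# ---------------------------------------------------------------------------
# spectral centralities

def eigenvector_centrality(graph: SimpleGraph, tol: float = 1e-10,
                           max_iter: int = 1000) -> dict:
    """Leading eigenvector of the binary adjacency by power iteration,
    max-normalised (top node = 1)."""
    vec = _leading_eigenvector(graph, tol, max_iter)
    top = vec.max()
    return dict(zip(graph.nodes, (vec / top).tolist()))


def hits_authority_hub(graph: SimpleGraph, tol: float = 1e-10,
                       max_iter: int = 1000) -> dict:
    """HITS scores; on an undirected graph authority = hub = the leading
    eigenvector direction with unit L2 norm."""
    vec = _leading_eigenvector(graph, tol, max_iter)
    vec = vec / np.linalg.norm(vec)
    return {u: (float(x), float(x)) for u, x in zip(graph.nodes, vec)}


def _leading_eigenvector(graph: SimpleGraph, tol: float, max_iter: int) -> np.ndarray:
    if graph.m == 0:
        raise UndefinedMetricError("eigenvector/HITS centrality is undefined without edges")
    # iterate on A + I: same eigenvectors as A, but the Perron root is
    # strictly dominant, so bipartite graphs cannot make the power
    # iteration oscillate between +/- the leading eigenvalue
    a = graph.adjacency_matrix(weighted=False) + np.eye(graph.n)
    vec = np.ones(graph.n) / math.sqrt(graph.n)
    for iteration in range(1, max_iter + 1):
        nxt = a @ vec
        norm = np.linalg.norm(nxt)
        if norm == 0:
            raise UndefinedMetricError("power iteration collapsed (no connected edges)")
        nxt /= norm
        if np.abs(nxt - vec).max() < tol:
            return nxt
        vec = nxt
    raise EstimationErrorWithCount(iteration)


class EstimationErrorWithCount(MetabonetError):
    def __init__(self, iterations: int):
        super().__init__(f"power iteration did not converge in {iterations} iterations")
        self.iterations = iterations


# ---------------------------------------------------------------------------
# local structure

def triangles_and_clustering(graph: SimpleGraph) -> dict:
    """Per node: (#edges among its neighbours, local clustering coefficient).

    Coefficient = triangles / (deg*(deg-1)/2); 0 when degree < 2.
    """
    out = {}
    for u in graph.nodes:
        nbrs = graph.adj[u]
        deg = len(nbrs)
        tri = 0
        for a in range(deg):
            for b in range(a + 1, deg):
                if graph.has_edge(nbrs[a], nbrs[b]):
                    tri += 1
        coeff = tri / (deg * (deg - 1) / 2.0) if deg >= 2 else 0.0
        out[u] = (tri, coeff)
    return out


# ---------------------------------------------------------------------------
# global statistics

@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network summary for one stratum."""

    n_nodes: int
    edge_count: int
    density: float
    diameter: int
    average_path_length: float
    average_clustering: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "edge_count": self.edge_count,
            "density": self.density,
            "diameter": self.diameter,
            "average_path_length": self.average_path_length,
            "average_clustering": self.average_clustering,
        }


def global_metrics(graph: SimpleGraph) -> GlobalMetrics:
    """Density, diameter, average path length and average clustering.

    Density is exact (m over n(n-1)/2).  On disconnected graphs the
    diameter is the largest finite eccentricity and the average path
    length averages finite pairwise distances only.
    """
    n = graph.n
    if n < 2:
        raise UndefinedMetricError("global metrics need at least two nodes")
    if graph.m == 0:
        raise UndefinedMetricError("diameter/path length are undefined for an edgeless graph")
    density = graph.m / (n * (n - 1) / 2.0)
    dist = shortest_path_distances(graph)
    iu = np.triu_indices(n, k=1)
    pairwise = dist[iu]
    finite = pairwise[np.isfinite(pairwise)]
    clustering = triangles_and_clustering(graph)
    avg_clust = float(np.mean([c for (_, c) in clustering.values()]))
    return GlobalMetrics(
        n_nodes=n,
        edge_count=graph.m,
        density=float(density),
        diameter=int(finite.max()),
        average_path_length=float(finite.mean()),
        average_clustering=avg_clust,
    )


# ---------------------------------------------------------------------------
# reporting

def metrics_table(graph: SimpleGraph, partition=None) -> pd.DataFrame:
    """One row per node with all nine node statistics, in node order.

    Columns mirror the standard stratified report: closeness, harmonic
    closeness, betweenness, authority, hub, modularity class, clustering
    coefficient, triangle count, eigenvector centrality.
    """
    from .community import louvain_communities  # local import, avoids cycle

    if partition is None:
        partition = louvain_communities(graph)
    assignment = getattr(partition, "assignment", partition)
    clo = closeness_centrality(graph)
    har = harmonic_closeness(graph)
    bet = betweenness_centrality(graph)
    tri = triangles_and_clustering(graph)
    if graph.m > 0:
        eig = eigenvector_centrality(graph)
        hits = hits_authority_hub(graph)
    else:
        eig = {u: 0.0 for u in graph.nodes}
        hits = {u: (0.0, 0.0) for u in graph.nodes}
    rows = []
    for u in graph.nodes:
        rows.append({
            "node": u,
            "closeness": clo[u],
            "harmonic_closeness": har[u],
            "betweenness": bet[u],
            "authority": hits[u][0],
            "hub": hits[u][1],
            "modularity_class": assignment[u],
            "clustering_coefficient": tri[u][1],
            "triangles": tri[u][0],
            "eigenvector": eig[u],
        })
    return pd.DataFrame(rows)


def rank_centrality(rows: pd.DataFrame, metric: str) -> list:
    """Nodes in descending order of a centrality metric.

    Ties keep the input (schema) order — the sort is stable.
    """
    if rows.empty:
        raise MetabonetError("empty metrics table")
    if metric not in rows.columns or metric == "node":
        raise ConfigurationError(
            f"unknown metric {metric!r}; expected one of {CENTRALITY_METRICS}"
        )
    order = rows.sort_values(metric, ascending=False, kind="stable")
    return order["node"].tolist()
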