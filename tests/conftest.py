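"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metabonet import NODES, CohortTable, SimpleGraph, SyntheticCohortParams, generate_cohort


def random_graph(rng: np.random.Generator, n_min: int = 3, n_max: int = 10,
                 require_connected: bool = False, signed: bool = True) -> SimpleGraph:
    """Random simple graph with at least one edge and signed weights."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        nodes = [f"n{i}" for i in range(n)]
        p = float(rng.uniform(0.25, 0.8))
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.uniform() < p:
                    w = float(rng.uniform(0.1, 1.0))
                    if signed and rng.uniform() < 0.4:
                        w = -w
                    edges.append((nodes[i], nodes[j], w))
        if not edges:
            continue
        g = SimpleGraph(nodes, edges)
        if require_connected and not _connected(g):
            continue
        return g


def _connected(g: SimpleGraph) -> bool:
    seen = {g.nodes[0]}
    stack = [g.nodes[0]]
    while stack:
        for v in g.adj[stack.pop()]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == g.n


def to_networkx(g: SimpleGraph):
    import networkx as nx

    gx = nx.Graph()
    gx.add_nodes_from(g.nodes)
    for u, v, w in g.edge_list():
        gx.add_edge(u, v, weight=w)
    return gx


def partial_corr_regression_oracle(x: np.ndarray) -> np.ndarray:
    """Partial correlations via the residual definition: corr of the
    residuals from regressing each member of a pair on all remaining
    variables (with intercept)."""
    n, p = x.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            design = np.column_stack([np.ones(n), x[:, others]])
            ri = x[:, i] - design @ np.linalg.lstsq(design, x[:, i], rcond=None)[0]
            rj = x[:, j] - design @ np.linalg.lstsq(design, x[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def floyd_warshall_oracle(g: SimpleGraph) -> np.ndarray:
    n = g.n
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, _ in g.edge_list():
        i, j = g.index(u), g.index(v)
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def set_partitions(items: list):
    """All set partitions (exhaustive modularity oracle)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def cohort_from_nodes(values: dict, glucose_units: str = "mg/dL") -> CohortTable:
    """Build a cohort table from per-node value lists, defaulting
    unspecified nodes to benign constants plus an index ramp (so no
    column is constant)."""
    n = len(next(iter(values.values())))
    data = {}
    for k, node in enumerate(NODES):
        if node in values:
            data[node] = list(values[node])
        elif node == "HTN":
            data[node] = [i % 2 for i in range(n)]
        else:
            data[node] = [50.0 + k + 0.5 * i for i in range(n)]
    return CohortTable(pd.DataFrame(data), glucose_units=glucose_units)


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default two-stratum cohort, seed 1."""
    return generate_cohort(SyntheticCohortParams(seed=1))
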