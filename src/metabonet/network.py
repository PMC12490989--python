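"""Partial-correlation (Gaussian graphical model) network estimation.

Within a stratum the association structure over the node variables is
summarised by the matrix of partial correlations: for nodes *i*, *j*,

    Rp_ij = -P_ij / sqrt(P_ii P_jj),      P = R^{-1},

where R is the Pearson correlation matrix.  Rp_ij measures the linear
association between *i* and *j* after adjusting for all remaining nodes,
and equals the correlation of the residuals from regressing *i* and *j*
on the other variables.  Each Rp is tested with the usual Student-t
statistic

    t = Rp * sqrt(df / (1 - Rp^2)),       df = n - 2 - g,

with g the number of conditioned variables (11 for the 13-node schema);
pairs with a two-sided p below the selection threshold (default 0.25, a
deliberately liberal screen that retains weak but potentially relevant
edges) form the signed weighted undirected network.  A magnitude rule
(|Rp| above a threshold) is available as an alternative selection mode.

The estimator follows the scikit-learn protocol: construct with
hyper-parameters, call :meth:`PartialCorrelationNetwork.fit` with an
(n_samples, n_nodes) table, read fitted attributes with trailing
underscores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    ConfigurationError,
    DegenerateVariableError,
    EstimationError,
    SampleSizeError,
)
from .graph import SimpleGraph
from .io import CohortTable

logger = logging.getLogger(__name__)

SELECTION_MODES = ("pvalue", "magnitude")

#: Smallest admissible eigenvalue of the correlation matrix.
_PD_TOL = 1e-10


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Coerce input to (values, node names)."""
    if isinstance(X, CohortTable):
        df = X.node_values()
        return df.to_numpy(dtype=float), list(df.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise EstimationError("expected a 2-D (samples x variables) table")
    return arr, [f"V{i}" for i in range(arr.shape[1])]


def compute_correlation_matrix(X) -> tuple[np.ndarray, int]:
    """Pearson correlation matrix over complete data.

    The binary hypertension flag enters as 0/1 numeric, i.e. its
    correlations are point-biserial.  Returns ``(R, n)``.

    Raises
    ------
    SampleSizeError
        if n < p + 2 (matrix not invertible / df non-positive).
    DegenerateVariableError
        naming the first constant column.
    """
    arr, names = _as_matrix(X)
    n, p = arr.shape
    if n < p + 2:
        raise SampleSizeError(
            f"need at least {p + 2} subjects for {p} variables, got {n}"
        )
    if np.isnan(arr).any():
        raise EstimationError("correlation requires complete data (missing values found)")
    sd = arr.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise DegenerateVariableError(
            f"node {names[constant[0]]!r} is constant; it cannot enter the network"
        )
    r = np.corrcoef(arr, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r, n


def compute_partial_correlations(corr: np.ndarray, ridge_lambda: float = 0.0) -> np.ndarray:
    """Partial correlations from a correlation matrix via its inverse.

    Optional ridge term (``ridge_lambda`` added to the diagonal before
    inversion, followed by re-standardisation) stabilises near-singular
    matrices from small strata; default 0 means plain inversion.
    """
    corr = np.asarray(corr, dtype=float)
    work = corr.copy()
    if ridge_lambda:
        work = work + ridge_lambda * np.eye(len(work))
        d = np.sqrt(np.diag(work))
        work = work / np.outer(d, d)
    eigmin = float(np.linalg.eigvalsh(work).min())
    if eigmin <= _PD_TOL:
        raise EstimationError(
            f"correlation matrix is singular or near-singular (min eigenvalue {eigmin:.3e}); "
            "consider the estimation.ridge_lambda option"
        )
    prec = np.linalg.inv(work)
    d = np.sqrt(np.diag(prec))
    rp = -prec / np.outer(d, d)
    rp = (rp + rp.T) / 2.0
    np.fill_diagonal(rp, 1.0)
    return np.clip(rp, -1.0, 1.0)


def edge_pvalue(rp, n: int, g: int):
    """Two-sided p-value for a partial correlation.

    t = rp * sqrt(df / (1 - rp^2)) with df = n - 2 - g degrees of freedom
    (g = number of conditioned variables).
    """
    df = n - 2 - g
    if df < 1:
        raise SampleSizeError(f"non-positive degrees of freedom (n={n}, g={g})")
    r = np.asarray(rp, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise EstimationError("|Rp| must be < 1 for the t-test")
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return float(p) if p.ndim == 0 else p


def select_edges(
    rp_matrix: np.ndarray,
    n: int,
    nodes: list[str] | tuple[str, ...],
    mode: str = "pvalue",
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Apply the edge-selection rule to every unordered node pair.

    Returns a DataFrame with one row per pair: ``node_i, node_j, rp,
    p_value, selected``.  In ``pvalue`` mode a pair is kept iff its
    two-sided p is below the threshold; in ``magnitude`` mode iff
    |Rp| exceeds it.  Weights stay signed.
    """
    if mode not in SELECTION_MODES:
        raise ConfigurationError(f"unknown selection mode {mode!r}; expected {SELECTION_MODES}")
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"selection threshold must be in (0, 1), got {threshold}")
    rp_matrix = np.asarray(rp_matrix, dtype=float)
    p_nodes = len(nodes)
    g = p_nodes - 2
    rows = []
    for i in range(p_nodes):
        for j in range(i + 1, p_nodes):
            rp = float(rp_matrix[i, j])
            pv = edge_pvalue(rp, n, g) if abs(rp) < 1.0 else 0.0
            if mode == "pvalue":
                keep = pv < threshold
            else:
                keep = abs(rp) > threshold
            keep = keep and rp != 0.0
            rows.append((nodes[i], nodes[j], rp, pv, bool(keep)))
    return pd.DataFrame(rows, columns=["node_i", "node_j", "rp", "p_value", "selected"])


def edges_to_graph(edges: pd.DataFrame, nodes) -> SimpleGraph:
    """Build the signed weighted undirected graph of selected edges."""
    sel = edges[edges["selected"]]
    return SimpleGraph(
        nodes,
        [(r.node_i, r.node_j, float(r.rp)) for r in sel.itertuples()],
    )


class PartialCorrelationNetwork(BaseEstimator):
    """Gaussian-graphical-model network estimator with per-edge screening.

    Parameters
    ----------
    selection_mode : {"pvalue", "magnitude"}, default="pvalue"
        ``pvalue`` keeps pairs with a two-sided partial-correlation
        p below ``threshold``; ``magnitude`` keeps |Rp| > ``threshold``.
    threshold : float, default=0.25
        Selection threshold (a liberal screen by design).
    ridge_lambda : float, default=0.0
        Diagonal ridge applied before matrix inversion.

    Attributes
    ----------
    nodes_ : list of str
        Variable names, in input column order.
    n_samples_ : int
        Sample size used.
    correlation_ : ndarray (p, p)
        Pearson correlation matrix.
    partial_corr_ : ndarray (p, p)
        Partial correlations (unit diagonal).
    pvalues_ : ndarray (p, p)
        Two-sided per-pair p-values (1 on the diagonal).
    edges_ : DataFrame
        One row per unordered pair with the selection flag.
    graph_ : SimpleGraph
        The selected signed weighted undirected network.
    """

    def __init__(self, selection_mode: str = "pvalue", threshold: float = 0.25,
                 ridge_lambda: float = 0.0):
        self.selection_mode = selection_mode
        self.threshold = threshold
        self.ridge_lambda = ridge_lambda

    def fit(self, X, y=None):
        arr, nodes = _as_matrix(X)
        corr, n = compute_correlation_matrix(arr)
        rp = compute_partial_correlations(corr, ridge_lambda=self.ridge_lambda)
        edges = select_edges(rp, n, nodes, mode=self.selection_mode,
                             threshold=self.threshold)
        p = len(nodes)
        pmat = np.ones((p, p))
        for row in edges.itertuples():
            i, j = nodes.index(row.node_i), nodes.index(row.node_j)
            pmat[i, j] = pmat[j, i] = row.p_value
        self.nodes_ = nodes
        self.n_features_in_ = p
        self.n_samples_ = n
        self.correlation_ = corr
        self.partial_corr_ = rp
        self.pvalues_ = pmat
        self.edges_ = edges
        self.graph_ = edges_to_graph(edges, nodes)
        logger.info(
            "estimated network: n=%d, %d/%d edges selected (%s < %g), "
            "correlation condition number %.3g",
            n, int(edges["selected"].sum()), len(edges), self.selection_mode,
            self.threshold, np.linalg.cond(corr),
        )
        return self

    @property
    def n_selected_edges_(self) -> int:
        return int(self.edges_["selected"].sum())
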