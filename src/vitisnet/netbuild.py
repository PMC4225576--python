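"""Thresholded Pearson correlation networks and their summary statistics.

A correlation network connects two metabolites when their Pearson coefficient
passes a joint threshold on magnitude (default r >= 0.9, positive sign mode)
and on the Benjamini-Hochberg q-value of the correlation test (default
q <= 0.01). Nodes exist only as edge endpoints ("viable network" convention):
a dataset without any significant pair yields a zero-node network, which is
exactly what happens to most column-permuted datasets at these thresholds.

Four network properties are reported: average node degree (mean edges per
node), density (realized fraction of all possible node pairs), clustering
coefficient (how mutually connected a node's neighbors are; mean local value
over nodes of degree >= 2 by default, global transitivity by flag) and
diameter (longest shortest path, computed on the largest connected component).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_profiles import ProfileMatrix

__all__ = [
    "CorrelationResult",
    "CorrelationNetwork",
    "NetworkStats",
    "pairwise_correlations",
    "correlation_qvalues",
    "build_network",
    "network_from_matrix",
    "network_stats",
    "stats_table",
    "nodes_from_degree",
    "density_from_counts",
]


@dataclass
class CorrelationResult:
    """Symmetric metabolite x metabolite matrices of r, p and pair counts."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


@dataclass
class CorrelationNetwork:
    """Undirected simple graph over metabolites with r/q edge attributes."""

    graph: nx.Graph
    r_min: float = 0.9
    q_max: float = 0.01
    sign_mode: str = "positive"
    provenance: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def viable(self) -> bool:
        """At least one edge (hence at least two nodes)."""
        return self.n_edges > 0

    def degree(self, node) -> int:
        if node not in self.graph:
            return 0
        return int(self.graph.degree(node))

    def edge_set(self) -> set[tuple]:
        return {tuple(sorted(e)) for e in self.graph.edges}


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    clustering: float
    diameter: float
    largest_component: int

    def as_dict(self) -> dict:
        return dict(
            n_nodes=self.n_nodes,
            n_edges=self.n_edges,
            avg_degree=self.avg_degree,
            density=self.density,
            clustering=self.clustering,
            diameter=self.diameter,
            largest_component=self.largest_component,
        )

    def get(self, parameter: str) -> float:
        return float(self.as_dict()[parameter])


def _p_from_r(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p for Pearson r via t = r * sqrt((n-2)/(1-r^2)), df = n-2."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.full(r.shape, np.nan)
    ok = np.isfinite(r) & (n >= 3)
    sat = ok & (np.abs(r) >= 1.0)
    p[sat] = 0.0
    reg = ok & ~sat
    if np.ndim(n) == 0:
        df = np.full(r.shape, n - 2.0)
    else:
        df = n - 2.0
    t = np.abs(r[reg]) * np.sqrt(df[reg] / (1.0 - r[reg] ** 2))
    p[reg] = 2.0 * stats.t.sf(t, df[reg])
    return p


def pairwise_correlations(
    data: ProfileMatrix | pd.DataFrame, min_pairs: int = 4
) -> CorrelationResult:
    """All-pairs Pearson correlations on pairwise-complete observations.

    Pairs with fewer than ``min_pairs`` complete observations or with zero
    variance in either column are flagged undefined (NaN r and p) and later
    excluded from the multiple-testing pool: they are non-tests, not
    failures. The diagonal is undefined (self-pairs are not tests).
    """
    values = data.values if isinstance(data, ProfileMatrix) else data
    mask = values.notna().to_numpy().astype(float)
    n = mask.T @ mask
    r = values.corr(method="pearson", min_periods=max(min_pairs, 3)).to_numpy()
    r[n < min_pairs] = np.nan
    p = _p_from_r(r, n)
    np.fill_diagonal(r, np.nan)
    np.fill_diagonal(p, np.nan)
    cols = values.columns
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=pd.DataFrame(n.astype(int), index=cols, columns=cols),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up on a flat vector; NaN entries stay NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def correlation_qvalues(p: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """BH adjustment applied jointly to all defined unique pairs of one dataset."""
    arr = p.to_numpy() if isinstance(p, pd.DataFrame) else np.asarray(p, dtype=float)
    m = arr.shape[0]
    iu = np.triu_indices(m, k=1)
    q_flat = bh_adjust(arr[iu])
    q = np.full_like(arr, np.nan)
    q[iu] = q_flat
    q.T[iu] = q_flat
    if isinstance(p, pd.DataFrame):
        return pd.DataFrame(q, index=p.index, columns=p.columns)
    return q


def _edge_predicate(r, q, r_min, q_max, sign_mode):
    if sign_mode == "positive":
        r_ok = r >= r_min
    elif sign_mode == "absolute":
        r_ok = np.abs(r) >= r_min
    else:
        raise ValueError(f"unknown sign mode {sign_mode!r}")
    return r_ok & (q <= q_max)


def build_network(
    r: pd.DataFrame,
    q: pd.DataFrame,
    r_min: float = 0.9,
    q_max: float = 0.01,
    sign_mode: str = "positive",
    provenance: str | None = None,
) -> CorrelationNetwork:
    """Threshold r and q matrices into a correlation network.

    An edge is kept iff r >= ``r_min`` (or |r| >= ``r_min`` under sign mode
    "absolute") and q <= ``q_max``; undefined pairs never form edges. Nodes
    are exactly the endpoints of retained edges, so the result may be empty.
    """
    names = list(r.columns)
    ra = r.to_numpy()
    qa = q.to_numpy()
    keep = _edge_predicate(
        np.where(np.isfinite(ra), ra, -np.inf),
        np.where(np.isfinite(qa), qa, np.inf),
        r_min,
        q_max,
        sign_mode,
    )
    graph = nx.Graph()
    iu = np.triu_indices(len(names), k=1)
    for i, j in zip(*iu):
        if keep[i, j]:
            graph.add_edge(names[i], names[j], r=float(ra[i, j]), q=float(qa[i, j]))
    return CorrelationNetwork(graph, r_min, q_max, sign_mode, provenance)


def network_from_matrix(
    data: ProfileMatrix | pd.DataFrame,
    r_min: float = 0.9,
    q_max: float = 0.01,
    sign_mode: str = "positive",
    min_pairs: int = 4,
    provenance: str | None = None,
) -> CorrelationNetwork:
    """Convenience: correlations -> q-values -> thresholded network."""
    corr = pairwise_correlations(data, min_pairs=min_pairs)
    q = correlation_qvalues(corr.p)
    return build_network(corr.r, q, r_min, q_max, sign_mode, provenance)


def network_stats(
    net: CorrelationNetwork | nx.Graph, clustering_mode: str = "local"
) -> NetworkStats:
    """The four network properties (plus counts and largest-component size).

    For an empty (zero-node) network the derived statistics are undefined
    (NaN) rather than zero. Clustering: mean local coefficient over nodes of
    degree >= 2 (``"local"``, default) or global transitivity (``"global"``).
    Diameter is the longest shortest path within the largest component.
    """
    graph = net.graph if isinstance(net, CorrelationNetwork) else net
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    if n_edges == 0:
        return NetworkStats(n_nodes, 0, np.nan, np.nan, np.nan, np.nan, 0)
    avg_degree = 2.0 * n_edges / n_nodes
    density = 2.0 * n_edges / (n_nodes * (n_nodes - 1)) if n_nodes > 1 else np.nan
    if clustering_mode == "local":
        local = nx.clustering(graph)
        eligible = [c for node, c in local.items() if graph.degree(node) >= 2]
        clustering = float(np.mean(eligible)) if eligible else np.nan
    elif clustering_mode == "global":
        clustering = float(nx.transitivity(graph))
    else:
        raise ValueError(f"unknown clustering mode {clustering_mode!r}")
    largest = max(nx.connected_components(graph), key=len)
    diameter = float(nx.diameter(graph.subgraph(largest)))
    return NetworkStats(
        n_nodes, n_edges, avg_degree, density, clustering, diameter, len(largest)
    )


def stats_table(networks: dict[str, CorrelationNetwork], clustering_mode="local") -> pd.DataFrame:
    """Stats for several networks as one table (nodes, edges, avg degree,
    density, clustering, diameter), one row per label."""
    rows = {}
    for label, net in networks.items():
        rows[label] = network_stats(net, clustering_mode).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "network"
    return df


# -- consistency utilities for published summary tables --------------------

def nodes_from_degree(n_edges: float, avg_degree: float) -> int:
    """Node count implied by an edge count and an average degree (2E/k)."""
    if avg_degree <= 0:
        raise ValueError("average degree must be positive")
    return int(round(2.0 * n_edges / avg_degree))


def density_from_counts(n_edges: int, n_nodes: int) -> float:
    """Density implied by edge and node counts: 2E / (N(N-1))."""
    if n_nodes < 2:
        raise ValueError("density needs at least two nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


# -- array fast path (used by the permutation test) ------------------------

def adjacency_from_matrix(
    X: np.ndarray,
    r_min: float,
    q_max: float,
    sign_mode: str = "positive",
) -> np.ndarray:
    """Boolean adjacency of the thresholded network for a complete matrix.

    ``X`` is samples x metabolites without missing values. q-values are
    recomputed from this matrix (the threshold predicate is part of the
    statistic, never frozen from other data).
    """
    n, m = X.shape
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float)
    dead = sd == 0
    r[dead, :] = np.nan
    r[:, dead] = np.nan
    iu = np.triu_indices(m, k=1)
    rv = r[iu]
    pv = _p_from_r(rv, n)
    qv = bh_adjust(pv)
    keep = _edge_predicate(
        np.where(np.isfinite(rv), rv, -np.inf),
        np.where(np.isfinite(qv), qv, np.inf),
        r_min,
        q_max,
        sign_mode,
    )
    adj = np.zeros((m, m), dtype=bool)
    adj[iu] = keep
    adj |= adj.T
    return adj


def parameter_from_adjacency(
    adj: np.ndarray, parameter: str, clustering_mode: str = "local"
) -> tuple[float, int]:
    """(parameter value, node count) from a boolean adjacency matrix.

    Any parameter of a non-viable (zero-edge) network is NaN. Degree-based
    parameters are computed directly; clustering and diameter go through
    networkx on the induced subgraph.
    """
    deg = adj.sum(axis=0)
    member = deg > 0
    n_nodes = int(member.sum())
    n_edges = int(adj[np.triu_indices(adj.shape[0], k=1)].sum())
    if n_edges == 0:
        return np.nan, 0
    if parameter == "n_nodes":
        return float(n_nodes), n_nodes
    if parameter == "n_edges":
        return float(n_edges), n_nodes
    if parameter == "avg_degree":
        return 2.0 * n_edges / n_nodes, n_nodes
    if parameter == "density":
        if n_nodes < 2:
            return np.nan, n_nodes
        return 2.0 * n_edges / (n_nodes * (n_nodes - 1)), n_nodes
    if parameter in ("clustering", "diameter"):
        graph = nx.from_numpy_array(adj[np.ix_(member, member)])
        value = network_stats(graph, clustering_mode)
        return value.get(parameter), n_nodes
    raise ValueError(f"unknown network parameter {parameter!r}")
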