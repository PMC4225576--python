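"""Set algebra on correlation networks and degree-based specificity measures.

Two networks over a shared metabolite namespace are compared by edge
identity: an edge is the unordered node pair, regardless of the correlation
magnitudes behind it (the r values are retained as attributes). From the
shared / A-specific / B-specific partition the module derives the symmetric
difference network, the "1 to R" specificity ratio between the two specific
edge counts, each node's condition-specific contribution (fraction of its
edges in one condition's network that the other condition lacks) and
between-network nodal-degree ratios.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import CorrelationNetwork

__all__ = [
    "NetworkComparison",
    "NodalDegreeRatio",
    "compare_networks",
    "specificity_ratio",
    "difference_network",
    "condition_specific_contribution",
    "nodal_degree_ratio",
    "specificity_table",
]


def _edge_key(edge) -> tuple:
    return tuple(sorted(edge))


@dataclass
class NetworkComparison:
    """Edge sets of two networks partitioned into shared / A- / B-specific."""

    label_a: str
    label_b: str
    shared: set = field(default_factory=set)
    a_specific: set = field(default_factory=set)
    b_specific: set = field(default_factory=set)
    #: edge -> (r in A or None, r in B or None)
    edge_r: dict = field(default_factory=dict)

    @property
    def universe(self) -> set:
        nodes: set = set()
        for edge in self.union:
            nodes.update(edge)
        return nodes

    @property
    def union(self) -> set:
        return self.shared | self.a_specific | self.b_specific

    @property
    def intersection(self) -> set:
        return set(self.shared)

    @property
    def symmetric_difference(self) -> set:
        return self.a_specific | self.b_specific

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_a_specific(self) -> int:
        return len(self.a_specific)

    @property
    def n_b_specific(self) -> int:
        return len(self.b_specific)

    def specific_degree(self, which: str) -> Counter:
        """Per-node tally of condition-specific edges for one side."""
        edges = {"a": self.a_specific, "b": self.b_specific}[which]
        tally: Counter = Counter()
        for u, v in edges:
            tally[u] += 1
            tally[v] += 1
        return tally


def compare_networks(
    a: CorrelationNetwork | nx.Graph,
    b: CorrelationNetwork | nx.Graph,
    label_a: str = "A",
    label_b: str = "B",
) -> NetworkComparison:
    """Partition the edge union of two networks by origin.

    Edge identity is the unordered node pair; r values from either side are
    carried along as attributes. Swapping the arguments swaps the A/B labels
    and nothing else.
    """
    ga = a.graph if isinstance(a, CorrelationNetwork) else a
    gb = b.graph if isinstance(b, CorrelationNetwork) else b
    edges_a = {_edge_key(e): ga.edges[e].get("r") for e in ga.edges}
    edges_b = {_edge_key(e): gb.edges[e].get("r") for e in gb.edges}
    comp = NetworkComparison(label_a, label_b)
    for edge in set(edges_a) | set(edges_b):
        in_a, in_b = edge in edges_a, edge in edges_b
        comp.edge_r[edge] = (edges_a.get(edge), edges_b.get(edge))
        if in_a and in_b:
            comp.shared.add(edge)
        elif in_a:
            comp.a_specific.add(edge)
        else:
            comp.b_specific.add(edge)
    return comp


def specificity_ratio(comparison: NetworkComparison, decimals: int = 2) -> float:
    """B-specific : A-specific edge count ratio, reported as the R of "1 to R".

    NaN when there are no A-specific edges (counts remain available on the
    comparison object).
    """
    if comparison.n_a_specific == 0:
        return float("nan")
    return round(comparison.n_b_specific / comparison.n_a_specific, decimals)


def difference_network(comparison: NetworkComparison, which: str = "a") -> nx.Graph:
    """Graph of the edges specific to one side of a comparison."""
    edges = {"a": comparison.a_specific, "b": comparison.b_specific}[which]
    graph = nx.Graph()
    for u, v in edges:
        r_a, r_b = comparison.edge_r[(u, v)]
        r = r_a if which == "a" else r_b
        graph.add_edge(u, v, r=r, origin=which)
    return graph


def _degree(net, node) -> int:
    graph = net.graph if isinstance(net, CorrelationNetwork) else net
    return int(graph.degree(node)) if node in graph else 0


def condition_specific_contribution(
    node,
    diff_net: nx.Graph | CorrelationNetwork,
    cond_net: CorrelationNetwork | nx.Graph,
) -> float:
    """Fraction of a node's edges in a condition network that are
    condition-specific: degree in the difference network over degree in the
    condition network. A node absent from the difference network contributes
    0; a node absent from the condition network is an error.
    """
    d_cond = _degree(cond_net, node)
    if d_cond == 0:
        raise ValueError(f"node {node!r} absent from the condition network")
    return _degree(diff_net, node) / d_cond


@dataclass
class NodalDegreeRatio:
    node: object
    degree_a: int
    degree_b: int
    ratio: float            # NaN when degree_b == 0
    flag: str | None        # "lost_all" / "gained_all" for 0-degree sides

    @property
    def defined(self) -> bool:
        return not np.isnan(self.ratio)


def nodal_degree_ratio(
    node, a: CorrelationNetwork | nx.Graph, b: CorrelationNetwork | nx.Graph
) -> NodalDegreeRatio:
    """Degree ratio of one node between two networks (a over b).

    A node connected in ``a`` but isolated from ``b`` is flagged
    ``"lost_all"`` (it lost every relation going from a's condition to b's,
    the undefined-ratio case); the converse is ``"gained_all"``. A node in
    neither network is an error.
    """
    da, db = _degree(a, node), _degree(b, node)
    if da == 0 and db == 0:
        raise ValueError(f"node {node!r} present in neither network")
    if db == 0:
        return NodalDegreeRatio(node, da, db, float("nan"), "lost_all")
    if da == 0:
        return NodalDegreeRatio(node, da, db, 0.0, "gained_all")
    return NodalDegreeRatio(node, da, db, da / db, None)


def specificity_table(
    comparison: NetworkComparison,
    a: CorrelationNetwork | nx.Graph,
    b: CorrelationNetwork | nx.Graph,
) -> pd.DataFrame:
    """Per-node specificity summary over the comparison universe.

    Columns: degree in each network, specific-degree tallies per side, and
    each side's condition-specific contribution (specific degree over the
    node's degree in that side's network; NaN when the node is absent there).
    """
    spec_a = comparison.specific_degree("a")
    spec_b = comparison.specific_degree("b")
    rows = []
    for node in sorted(comparison.universe, key=str):
        da, db = _degree(a, node), _degree(b, node)
        rows.append(
            dict(
                node=node,
                degree_a=da,
                degree_b=db,
                specific_a=spec_a.get(node, 0),
                specific_b=spec_b.get(node, 0),
                contribution_a=spec_a.get(node, 0) / da if da else np.nan,
                contribution_b=spec_b.get(node, 0) / db if db else np.nan,
            )
        )
    return pd.DataFrame(rows)
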