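"""Community detection on correlation networks and compound-class enrichment.

Communities are detected topologically (greedy modularity maximization by
default, deterministic) or imposed from the compound-class annotation; either
partition can then be tested for over-representation of compound classes with
a one-sided hypergeometric test, BH-adjusted across all (community, class)
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .netbuild import CorrelationNetwork, bh_adjust

__all__ = [
    "CommunityPartition",
    "detect_communities",
    "annotation_partition",
    "class_enrichment",
]


@dataclass
class CommunityPartition:
    assignment: dict            # node -> community id (int, stable ordering)
    method: str
    seed: int | None
    modularity: float

    @property
    def communities(self) -> dict:
        groups: dict = {}
        for node, cid in self.assignment.items():
            groups.setdefault(cid, set()).add(node)
        return groups

    def sizes(self) -> dict:
        return {cid: len(members) for cid, members in self.communities.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items(), key=lambda kv: (kv[1], str(kv[0])))
        return pd.DataFrame(rows, columns=["node", "community"])


def _canonical_ids(groups: list[set]) -> dict:
    """Number communities by size (desc), then lexicographically smallest member."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(map(str, g))))
    return {node: cid for cid, group in enumerate(ordered) for node in group}


def detect_communities(
    net: CorrelationNetwork | nx.Graph,
    method: str = "greedy-modularity",
    seed: int | None = None,
) -> CommunityPartition:
    """Partition the network into communities.

    ``greedy-modularity`` (default) is deterministic; ``louvain`` uses the
    seed. Community ids are canonicalized (largest community first, ties by
    smallest member), so the partition is invariant to node input order.
    Empty networks are an error; singleton components cannot occur because
    nodes exist only as edge endpoints.
    """
    graph = net.graph if isinstance(net, CorrelationNetwork) else net
    if graph.number_of_edges() == 0:
        raise ValueError("cannot detect communities on an empty network")
    if method == "greedy-modularity":
        groups = [set(g) for g in nx.community.greedy_modularity_communities(graph)]
    elif method == "louvain":
        groups = [set(g) for g in nx.community.louvain_communities(graph, seed=seed)]
    else:
        raise ValueError(f"unknown community method {method!r}")
    assignment = _canonical_ids(groups)
    score = nx.community.modularity(graph, groups)
    return CommunityPartition(assignment, method, seed, float(score))


def annotation_partition(
    net: CorrelationNetwork | nx.Graph, annotations: Mapping[str, str]
) -> CommunityPartition:
    """Partition imposed by compound class rather than topology.

    Every network node is assigned the community of its annotated class
    (unannotated nodes fall into "other"); modularity of that partition is
    reported so imposed and detected structure can be compared.
    """
    graph = net.graph if isinstance(net, CorrelationNetwork) else net
    if graph.number_of_edges() == 0:
        raise ValueError("cannot partition an empty network")
    by_class: dict = {}
    for node in graph.nodes:
        by_class.setdefault(annotations.get(node, "other"), set()).add(node)
    groups = list(by_class.values())
    assignment = _canonical_ids(groups)
    score = nx.community.modularity(graph, groups)
    return CommunityPartition(assignment, "annotation", None, float(score))


def class_enrichment(
    partition: CommunityPartition, annotations: Mapping[str, str] | pd.DataFrame
) -> pd.DataFrame:
    """Hypergeometric over-representation of compound classes per community.

    For a community of size n in a network of N nodes, of which K belong to a
    class and k of those sit inside the community, the one-sided p-value is
    P(X >= k) for X ~ Hypergeometric(N, K, n). BH adjustment runs across all
    (community, class) rows. Unannotated nodes count as class "other".
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = annotations["compound_class"].to_dict()
    nodes = list(partition.assignment)
    classes = {node: annotations.get(node, "other") for node in nodes}
    N = len(nodes)
    class_sizes: dict = {}
    for cls in classes.values():
        class_sizes[cls] = class_sizes.get(cls, 0) + 1
    rows = []
    for cid, members in sorted(partition.communities.items()):
        n = len(members)
        for cls in sorted(class_sizes):
            K = class_sizes[cls]
            k = sum(1 for node in members if classes[node] == cls)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append(
                dict(community=cid, compound_class=cls, k=k, K=K, n=n, N=N, p=p)
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
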