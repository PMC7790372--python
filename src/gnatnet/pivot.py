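"""Cluster-level "pivot" contraction of an SSN and its topology statistics.

Each detected cluster becomes a single node; two pivot nodes are joined
when any SSN edge crosses between their member sets, or when the clusters
share a member (overlapping clusters are at least as related as clusters
joined by a single cross edge).  The pivot network is unweighted and
undirected; topology is summarised by node degree, Brandes betweenness
centrality (normalised by (n-1)(n-2)/2), and connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .clustering import Clustering
from .network import SimilarityNetwork


@dataclass
class TopologyReport:
    degree: dict
    betweenness: dict
    components: list[set]


def contract(ssn: SimilarityNetwork, clustering: Clustering) -> nx.Graph:
    """Contract a clustered SSN into the pivot network.

    Nodes are cluster ids (with ``size`` and ``label`` attributes); SSN
    nodes assigned to no cluster are ignored.
    """
    pivot = nx.Graph()
    for cluster in clustering.clusters:
        pivot.add_node(cluster.cluster_id, size=cluster.size, label=cluster.label)
    membership = clustering.membership()
    # shared members induce pivot edges
    for node, cluster_ids in membership.items():
        ids = sorted(cluster_ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                pivot.add_edge(a, b)
    # inter-cluster SSN edges
    for u, v in ssn.graph.edges:
        for a in membership.get(u, ()):
            for b in membership.get(v, ()):
                if a != b:
                    pivot.add_edge(*sorted((a, b)))
    return pivot


def analyze_topology(graph: nx.Graph) -> TopologyReport:
    """Degree, normalised betweenness, and components (largest first).

    Betweenness is the fraction of all-pairs shortest paths through each
    node, normalised by (n-1)(n-2)/2; pairs in different components
    contribute nothing.
    """
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    components = sorted(
        (set(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), sorted(map(str, c))),
    )
    return TopologyReport(
        degree=dict(graph.degree),
        betweenness=betweenness,
        components=components,
    )


def write_topology_tsv(
    graph: nx.Graph, report: TopologyReport, path: str | Path
) -> None:
    """Topology table: cluster_id, size, degree, betweenness, component_id."""
    component_of = {}
    for idx, comp in enumerate(report.components, start=1):
        for node in comp:
            component_of[node] = idx
    with open(path, "w") as fh:
        fh.write("cluster_id\tsize\tdegree\tbetweenness\tcomponent_id\n")
        for node in sorted(graph.nodes):
            size = graph.nodes[node].get("size", "")
            fh.write(
                f"{node}\t{size}\t{report.degree[node]}\t"
                f"{report.betweenness[node]:.6f}\t{component_of[node]}\n"
            )
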