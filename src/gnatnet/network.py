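"""Sequence similarity network construction and serialisation.

An SSN is an undirected graph over sequence ids; an edge is drawn for each
pairwise hit passing both thresholds (E-value maximum and minimum edge
score, where the edge score is -log10 of the E-value floored at 1e-180).
Edges are weighted by percent identity over aligned columns, which is the
weight the downstream density-based clustering consumes.  The convergence
ratio |E| / (n(n-1)/2) summarises global divergence of the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .align import PairwiseHit, edge_score
from .records import SequenceRecord


@dataclass
class SimilarityNetwork:
    """Thresholded, identity-weighted sequence similarity network."""

    graph: nx.Graph
    evalue_max: float
    score_min: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def convergence_ratio(self) -> float:
        n = self.n_nodes
        possible = n * (n - 1) / 2
        return self.n_edges / possible if possible else 0.0

    def largest_component(self) -> set[str]:
        if self.n_nodes == 0:
            return set()
        return max(nx.connected_components(self.graph), key=len)


def build_ssn(
    hits: Iterable[PairwiseHit],
    evalue_max: float,
    score_min: float,
    records: Sequence[SequenceRecord] | None = None,
) -> SimilarityNetwork:
    """Build the SSN from pairwise hits.

    An edge is kept iff ``evalue <= evalue_max`` and
    ``-log10(max(evalue, 1e-180)) >= score_min``.  When ``records`` is
    given, every record becomes a node (so isolated sequences are
    represented) and node metadata is attached; otherwise nodes are the
    ids appearing in passing hits.
    """
    graph = nx.Graph()
    if records is not None:
        for rec in records:
            graph.add_node(
                rec.id, status=rec.status, label=rec.label, taxon=rec.taxon
            )
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        score = edge_score(hit.evalue)
        if hit.evalue <= evalue_max and score >= score_min:
            graph.add_edge(
                hit.query_id,
                hit.subject_id,
                weight=hit.pct_identity,
                evalue=hit.evalue,
                edge_score=score,
            )
    return SimilarityNetwork(graph=graph, evalue_max=evalue_max, score_min=score_min)


def write_edge_tsv(ssn: SimilarityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tpct_identity\tevalue\tedge_score\n")
        for u, v, data in sorted(ssn.graph.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data['weight']:.2f}\t{data['evalue']:.3e}\t"
                f"{data['edge_score']:.2f}\n"
            )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_node_table(ssn: SimilarityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstatus\tlabel\ttaxon\tdegree\n")
        for node in sorted(ssn.graph.nodes):
            data = ssn.graph.nodes[node]
            fh.write(
                f"{node}\t{data.get('status', '')}\t{data.get('label', '')}\t"
                f"{data.get('taxon', '')}\t{ssn.graph.degree[node]}\n"
            )


def write_xgmml(graph: nx.Graph, path: str | Path, name: str = "network") -> None:
    """Minimal XGMML export for Cytoscape compatibility."""
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write(
            f'<graph label="{name}" directed="0" '
            'xmlns="http://www.cs.rpi.edu/XGMML">\n'
        )
        index = {node: i for i, node in enumerate(sorted(graph.nodes))}
        for node, i in index.items():
            fh.write(f'  <node id="{i}" label="{node}"/>\n')
        for u, v in sorted(graph.edges):
            fh.write(f'  <edge source="{index[u]}" target="{index[v]}"/>\n')
        fh.write("</graph>\n")
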