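"""Small-world diagnostics of SSN components and phylogeny dataset selection.

The small-worldness index of a connected graph is

    sigma = (C / C_rand) / (L / L_rand)

where C is the average clustering coefficient, L the average shortest path
length, and the reference values are means over degree-preserving rewired
copies of the graph (double-edge swaps).  sigma > 1 is the conventional
small-world call.  A grid of SSN thresholds is scanned for the network
whose largest connected component is small-world and largest, and that
component supplies per-cluster representative sequences (curated members
preferred) for external phylogenetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .align import PairwiseHit
from .clustering import Clustering
from .network import build_ssn
from .records import SequenceRecord


@dataclass
class SmallWorldStats:
    C: float
    L: float
    C_rand: float
    L_rand: float
    sigma: float
    n_ref: int
    seed: int

    @property
    def is_smallworld(self) -> bool:
        return self.sigma > 1.0


@dataclass
class GridRow:
    evalue_max: float
    score_min: float
    n_nodes: int
    n_edges: int
    largest_component_size: int
    sigma: float
    is_smallworld: bool
    component: set


def rewire_preserving_degree(
    graph: nx.Graph, rng: np.random.Generator, swaps_per_edge: int = 10
) -> nx.Graph:
    """Degree-preserving randomisation by attempted double-edge swaps.

    ``swaps_per_edge * |E|`` swaps are attempted; an attempt picking edges
    (a, b) and (c, d) rewires them to (a, d) and (c, b) only when neither
    new edge exists and no self-loop arises.  On swap-saturated graphs
    (e.g. complete graphs) every attempt fails and the graph is returned
    unchanged, which is the correct reference.
    """
    rewired = nx.Graph()
    rewired.add_nodes_from(graph.nodes)
    rewired.add_edges_from(graph.edges)
    edges = [tuple(e) for e in rewired.edges]
    n_attempts = swaps_per_edge * len(edges)
    for _ in range(n_attempts):
        if len(edges) < 2:
            break
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if rewired.has_edge(a, d) or rewired.has_edge(c, b):
            continue
        rewired.remove_edge(a, b)
        rewired.remove_edge(c, d)
        rewired.add_edge(a, d)
        rewired.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return rewired


def smallworldness(graph: nx.Graph, n_ref: int = 10, seed: int = 0) -> SmallWorldStats:
    """Small-worldness sigma against degree-preserving rewired references.

    The input must be connected with at least 4 nodes (pass the largest
    component of a fragmented network).  Disconnected rewired references
    are measured on their largest component.
    """
    if graph.number_of_nodes() < 4:
        raise ValueError("smallworldness needs at least 4 nodes")
    if not nx.is_connected(graph):
        raise ValueError("graph must be connected; pass the largest component")
    C = nx.average_clustering(graph)
    L = nx.average_shortest_path_length(graph)
    rng = np.random.default_rng(seed)
    C_refs, L_refs = [], []
    for _ in range(n_ref):
        ref = rewire_preserving_degree(graph, rng)
        if not nx.is_connected(ref):
            ref = ref.subgraph(max(nx.connected_components(ref), key=len))
        C_refs.append(nx.average_clustering(ref))
        L_refs.append(nx.average_shortest_path_length(ref))
    C_rand = float(np.mean(C_refs))
    L_rand = float(np.mean(L_refs))
    # A vanishing reference clustering coefficient would blow sigma up;
    # floor it at one closed triple's worth for the graph size.
    C_rand_floor = max(C_rand, 1e-9)
    sigma = (C / C_rand_floor) / (L / L_rand) if L_rand > 0 else 0.0
    return SmallWorldStats(
        C=C, L=L, C_rand=C_rand, L_rand=L_rand, sigma=sigma, n_ref=n_ref, seed=seed
    )


def grid_scan(
    hits: Sequence[PairwiseHit],
    grid: Iterable[tuple[float, float]],
    records: Sequence[SequenceRecord] | None = None,
    n_ref: int = 10,
    seed: int = 0,
) -> list[GridRow]:
    """Build one SSN per (evalue_max, score_min) grid point and score it.

    ``hits`` must have been computed once at the loosest E-value of the
    grid; each row reports the largest component and its small-worldness.
    """
    rows = []
    for evalue_max, score_min in grid:
        ssn = build_ssn(hits, evalue_max, score_min, records=records)
        component = ssn.largest_component()
        if len(component) >= 4:
            stats = smallworldness(ssn.graph.subgraph(component), n_ref=n_ref, seed=seed)
            sigma, is_sw = stats.sigma, stats.is_smallworld
        else:
            sigma, is_sw = 0.0, False
        rows.append(
            GridRow(
                evalue_max=evalue_max,
                score_min=score_min,
                n_nodes=ssn.n_nodes,
                n_edges=ssn.n_edges,
                largest_component_size=len(component),
                sigma=sigma,
                is_smallworld=is_sw,
                component=component,
            )
        )
    return rows


def select_phylogeny_component(rows: Sequence[GridRow]) -> tuple[GridRow, bool]:
    """Pick the grid row whose largest component is small-world and largest.

    Ties are broken by stricter (smaller) E-value, then higher score
    minimum.  When no row qualifies, the row with maximal sigma is
    returned together with a ``fallback`` flag set to True.
    """
    if not rows:
        raise ValueError("empty scan table")
    qualifying = [r for r in rows if r.is_smallworld]
    if qualifying:
        best = sorted(
            qualifying,
            key=lambda r: (-r.largest_component_size, r.evalue_max, -r.score_min),
        )[0]
        return best, False
    best = max(rows, key=lambda r: r.sigma)
    return best, True


def select_representatives(
    clustering: Clustering,
    component: set,
    records: Sequence[SequenceRecord],
    k: int = 3,
    seed: int = 0,
) -> dict[int, list[str]]:
    """Pick up to ``k`` representative sequences per cluster in a component.

    Curated members come first (lexicographically smallest ids when more
    than ``k`` exist); remaining slots are filled by seeded uniform
    sampling of unreviewed members.  Clusters smaller than ``k``
    contribute all their members.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_id = {rec.id: rec for rec in records}
    rng = np.random.default_rng(seed)
    chosen: dict[int, list[str]] = {}
    for cluster in clustering.clusters:
        members = sorted(cluster.members & component) if component else sorted(cluster.members)
        if not members:
            continue
        curated = [m for m in members if by_id[m].is_curated]
        others = [m for m in members if not by_id[m].is_curated]
        picks = curated[:k]
        remaining = k - len(picks)
        if remaining > 0 and others:
            n_draw = min(remaining, len(others))
            drawn = rng.choice(others, size=n_draw, replace=False)
            picks.extend(sorted(str(d) for d in drawn))
        chosen[cluster.cluster_id] = picks
    return chosen


def write_grid_tsv(rows: Sequence[GridRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "evalue_max\tscore_min\tn_nodes\tn_edges\t"
            "largest_component_size\tsigma\tis_smallworld\n"
        )
        for r in rows:
            fh.write(
                f"{r.evalue_max:.1e}\t{r.score_min:g}\t{r.n_nodes}\t{r.n_edges}\t"
                f"{r.largest_component_size}\t{r.sigma:.4f}\t"
                f"{int(r.is_smallworld)}\n"
            )
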