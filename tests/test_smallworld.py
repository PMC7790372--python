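import networkx as nx
import numpy as np
import pytest

from gnatnet.align import all_vs_all
from gnatnet.clustering import Cluster, Clustering
from gnatnet.records import SequenceRecord
from gnatnet.smallworld import (
    GridRow,
    grid_scan,
    rewire_preserving_degree,
    select_phylogeny_component,
    select_representatives,
    smallworldness,
)


def test_complete_graph_sigma_is_one():
    stats = smallworldness(nx.complete_graph(6), n_ref=5, seed=0)
    assert stats.C == 1.0
    assert stats.L == 1.0
    assert stats.sigma == pytest.approx(1.0)


def test_rewiring_preserves_degrees():
    rng = np.random.default_rng(0)
    graph = nx.gnp_random_graph(30, 0.2, seed=1)
    rewired = rewire_preserving_degree(graph, rng)
    assert dict(rewired.degree) == dict(graph.degree)
    assert rewired.number_of_edges() == graph.number_of_edges()


def test_watts_strogatz_is_smallworld():
    graph = nx.connected_watts_strogatz_graph(100, 8, 0.05, seed=4)
    stats = smallworldness(graph, n_ref=5, seed=0)
    assert stats.is_smallworld
    assert stats.sigma > 1.0


def test_disconnected_input_rejected():
    graph = nx.Graph([(0, 1), (2, 3)])
    with pytest.raises(ValueError, match="connected"):
        smallworldness(graph, n_ref=2, seed=0)


def test_sigma_invariant_under_relabelling():
    graph = nx.connected_watts_strogatz_graph(60, 6, 0.1, seed=2)
    stats = smallworldness(graph, n_ref=5, seed=9)
    relabelled = nx.relabel_nodes(graph, {i: f"x{i}" for i in graph.nodes})
    stats2 = smallworldness(relabelled, n_ref=5, seed=9)
    assert stats2.sigma == pytest.approx(stats.sigma, rel=0.25)


def test_grid_scan_monotone_component(small_superfamily):
    records, _ = small_superfamily
    hits = all_vs_all(records, evalue_cutoff=1e-2)
    grid = [(1e-2, 2.0), (1e-5, 5.0), (1e-20, 20.0), (1e-40, 40.0)]
    rows = grid_scan(hits, grid, records=records, n_ref=3, seed=0)
    sizes = [r.largest_component_size for r in rows]
    assert sizes == sorted(sizes, reverse=True)
    edge_counts = [r.n_edges for r in rows]
    assert edge_counts == sorted(edge_counts, reverse=True)


def row(size, sigma, evalue=1e-5, score=5.0):
    return GridRow(evalue, score, 100, 200, size, sigma, sigma > 1, set(range(size)))


def test_select_component_rules():
    chosen, fallback = select_phylogeny_component([row(50, 1.5), row(80, 1.2)])
    assert chosen.largest_component_size == 80 and not fallback

    only = row(40, 2.0)
    chosen, fallback = select_phylogeny_component([only, row(90, 0.8)])
    assert chosen is only and not fallback

    chosen, fallback = select_phylogeny_component([row(40, 0.9), row(90, 0.5)])
    assert chosen.sigma == 0.9 and fallback

    with pytest.raises(ValueError):
        select_phylogeny_component([])


def make_records(n_curated, n_unreviewed):
    residues = "MDELWKNAGHETSYVKRPLQ" * 3
    recs = [
        SequenceRecord(f"sw{i}", residues, status="curated")
        for i in range(n_curated)
    ]
    recs += [SequenceRecord(f"tr{i}", residues) for i in range(n_unreviewed)]
    return recs


def test_select_representatives_rules():
    records = make_records(2, 5)
    clustering = Clustering(
        clusters=[Cluster(1, {r.id for r in records}, 1.0, 1.0)]
    )
    component = {r.id for r in records}
    picks = select_representatives(clustering, component, records, k=3, seed=0)
    assert len(picks[1]) == 3
    assert {"sw0", "sw1"} <= set(picks[1])

    # more curated than k: lexicographically smallest ids win
    records4 = make_records(4, 0)
    clustering4 = Clustering(clusters=[Cluster(1, {r.id for r in records4}, 1, 1)])
    picks4 = select_representatives(clustering4, {r.id for r in records4}, records4, k=3, seed=0)
    assert picks4[1] == ["sw0", "sw1", "sw2"]

    # tiny cluster contributes everything
    records2 = make_records(0, 2)
    clustering2 = Clustering(clusters=[Cluster(1, {r.id for r in records2}, 1, 1)])
    picks2 = select_representatives(clustering2, {r.id for r in records2}, records2, k=3, seed=0)
    assert sorted(picks2[1]) == ["tr0", "tr1"]


def test_select_representatives_deterministic():
    records = make_records(1, 10)
    clustering = Clustering(clusters=[Cluster(1, {r.id for r in records}, 1, 1)])
    component = {r.id for r in records}
    a = select_representatives(clustering, component, records, k=3, seed=42)
    b = select_representatives(clustering, component, records, k=3, seed=42)
    assert a == b
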