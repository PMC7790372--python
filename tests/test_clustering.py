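import networkx as nx
import numpy as np
import pytest

from gnatnet.clustering import (
    Cluster,
    Clustering,
    ClusteringParams,
    brute_force_best_cluster,
    clustering_f1,
    cohesiveness,
    detect_clusters,
    grow_cluster,
)

from .conftest import random_connected_weighted_graph


def unit_graph(edges):
    graph = nx.Graph()
    for u, v in edges:
        graph.add_edge(u, v, weight=1.0)
    return graph


def two_triangles_with_bridge():
    return unit_graph(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
    )


def test_cohesiveness_examples():
    triangle = unit_graph([("a", "b"), ("b", "c"), ("a", "c")])
    assert cohesiveness(triangle, {"a", "b", "c"}, 0.0) == 1.0
    path = unit_graph([("a", "b"), ("b", "c")])
    assert cohesiveness(path, {"a", "b"}, 0.0) == 0.5
    single = unit_graph([("a", "b")])
    assert cohesiveness(single, {"a"}, 2.0) == 0.0
    with pytest.raises(ValueError):
        cohesiveness(triangle, set(), 0.0)


def test_grow_stops_at_triangle():
    graph = two_triangles_with_bridge()
    cluster = grow_cluster(graph, "a", ClusteringParams(min_size=1, penalty=0.5))
    assert cluster.members == {"a", "b", "c"}


def test_grow_takes_whole_clique():
    k5 = unit_graph([(i, j) for i in range(5) for j in range(i + 1, 5)])
    cluster = grow_cluster(k5, 0, ClusteringParams(min_size=1, penalty=0.0))
    assert cluster.members == set(range(5))
    assert cluster.cohesiveness == 1.0


def test_isolated_seed_stays_single():
    graph = nx.Graph()
    graph.add_node("lonely")
    cluster = grow_cluster(graph, "lonely", ClusteringParams(min_size=1))
    assert cluster.members == {"lonely"}


def test_growth_trajectory_is_monotone():
    """Each accepted greedy step strictly increases cohesiveness."""
    rng = np.random.default_rng(0)
    params = ClusteringParams(min_size=1, penalty=1.0)
    for _ in range(10):
        graph = random_connected_weighted_graph(rng)
        seed = sorted(graph.nodes)[0]
        cluster = grow_cluster(graph, seed, params)
        assert cluster.cohesiveness >= cohesiveness(graph, {seed}, 1.0) - 1e-12


def test_detect_two_cliques():
    graph = unit_graph(
        [(f"a{i}", f"a{j}") for i in range(10) for j in range(i + 1, 10)]
        + [(f"b{i}", f"b{j}") for i in range(10) for j in range(i + 1, 10)]
    )
    clustering = detect_clusters(graph, ClusteringParams(min_size=10, min_density=0.0))
    assert [c.cluster_id for c in clustering.clusters] == [1, 2]
    assert sorted(c.size for c in clustering.clusters) == [10, 10]
    assert clustering.unassigned == set()


def test_min_size_filters_k9():
    graph = unit_graph(
        [(f"a{i}", f"a{j}") for i in range(9) for j in range(i + 1, 9)]
    )
    clustering = detect_clusters(graph, ClusteringParams(min_size=10))
    assert clustering.clusters == []
    assert len(clustering.unassigned) == 9


def test_every_member_connected_into_cluster():
    rng = np.random.default_rng(5)
    for _ in range(10):
        graph = random_connected_weighted_graph(rng)
        clustering = detect_clusters(graph, ClusteringParams(min_size=2, min_density=0.0))
        for cluster in clustering.clusters:
            for member in cluster.members:
                assert any(
                    other in cluster.members for other in graph.neighbors(member)
                )


def test_node_order_invariance():
    rng = np.random.default_rng(11)
    graph = random_connected_weighted_graph(rng, n_max=9)
    params = ClusteringParams(min_size=2, min_density=0.0)
    result = detect_clusters(graph, params)
    shuffled = nx.Graph()
    order = list(graph.nodes)
    rng.shuffle(order)
    shuffled.add_nodes_from(order)
    shuffled.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True)
    )
    result2 = detect_clusters(shuffled, params)
    assert [c.members for c in result.clusters] == [c.members for c in result2.clusters]


def test_brute_force_examples():
    single_edge = unit_graph([("a", "b")])
    best = brute_force_best_cluster(single_edge, p=0.0)
    assert best.members == {"a", "b"}
    assert best.cohesiveness == 1.0
    with pytest.raises(ValueError):
        brute_force_best_cluster(unit_graph([(i, i + 1) for i in range(16)]), 1.0)


def test_greedy_never_beats_oracle():
    rng = np.random.default_rng(2)
    params = ClusteringParams(min_size=1, penalty=1.0)
    matches = 0
    n_graphs = 25
    for _ in range(n_graphs):
        graph = random_connected_weighted_graph(rng, n_max=8)
        oracle = brute_force_best_cluster(graph, p=1.0)
        seed = max(
            oracle.members,
            key=lambda n: (sum(d.get("weight", 1) for _, _, d in graph.edges(n, data=True)), str(n)),
        )
        greedy = grow_cluster(graph, seed, params)
        assert greedy.cohesiveness <= oracle.cohesiveness + 1e-9
        if abs(greedy.cohesiveness - oracle.cohesiveness) <= 1e-9:
            matches += 1
    assert matches >= 0.8 * n_graphs


def test_clustering_f1_examples():
    truth = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
    perfect = Clustering(
        clusters=[
            Cluster(1, {f"a{i}" for i in range(5)}, 1.0, 1.0),
            Cluster(2, {f"b{i}" for i in range(5)}, 1.0, 1.0),
        ]
    )
    assert clustering_f1(perfect, truth) == 1.0
    giant = Clustering(clusters=[Cluster(1, set(truth), 1.0, 1.0)])
    assert clustering_f1(giant, truth) == pytest.approx(2 / 3)
    assert clustering_f1(Clustering(clusters=[]), truth) == 0.0


def test_duplicate_clusters_merge():
    graph = unit_graph(
        [(f"a{i}", f"a{j}") for i in range(6) for j in range(i + 1, 6)]
    )
    clustering = detect_clusters(
        graph, ClusteringParams(min_size=2, overlap_omega=0.8, min_density=0.0)
    )
    assert len(clustering.clusters) == 1
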