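"""Shared fixtures: small synthetic superfamilies and random graph factories."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from gnatnet.records import AMINO_ACIDS, SequenceRecord
from gnatnet.synthetic import FamilySpec, generate_superfamily


@pytest.fixture(scope="session")
def small_superfamily():
    """3 families x 10 sequences with planted motifs, fixed seed."""
    specs = [
        FamilySpec(
            "famA", 10,
            motifs=[("a1a2", "YYAEKKWPG", 20), ("b4", "LHVQTSN", 60)],
            target_within_identity=0.75,
        ),
        FamilySpec("famB", 10, target_within_identity=0.75),
        FamilySpec("famC", 10, target_within_identity=0.75),
    ]
    return generate_superfamily(specs, seed=7)


def random_sequence(rng: np.random.Generator, length: int = 150) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_records(rng: np.random.Generator, n: int, length: int = 150, prefix: str = "r"):
    return [
        SequenceRecord(f"{prefix}{i}", random_sequence(rng, length))
        for i in range(n)
    ]


def random_connected_weighted_graph(
    rng: np.random.Generator, n_max: int = 10, weighted: bool = True
) -> nx.Graph:
    """A random connected graph with up to n_max nodes, weights in (0, 1]."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        p = float(rng.uniform(0.3, 0.8))
        graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if graph.number_of_edges() and nx.is_connected(graph):
            break
    relabel = {i: f"n{i:02d}" for i in graph.nodes}
    graph = nx.relabel_nodes(graph, relabel)
    for u, v in graph.edges:
        graph[u][v]["weight"] = float(rng.uniform(0.1, 1.0)) if weighted else 1.0
    return graph
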