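"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: the alignment oracle is
a from-scratch affine-gap dynamic program (validated below against full
path enumeration on tiny inputs), and the betweenness oracle counts
shortest paths explicitly.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx

# Hand-copied BLOSUM62 entries for a 4-letter test alphabet.
BLOSUM62_4 = {
    ("L", "L"): 4, ("V", "V"): 4, ("E", "E"): 5, ("K", "K"): 5,
    ("L", "V"): 1, ("L", "E"): -3, ("L", "K"): -2,
    ("V", "E"): -2, ("V", "K"): -2, ("E", "K"): 1,
}


def _sub(a: str, b: str) -> int:
    return BLOSUM62_4.get((a, b), BLOSUM62_4.get((b, a)))


def sw_oracle(seq_a: str, seq_b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal Smith-Waterman score, affine gaps (gap of length g costs
    open + g*extend), by an independent three-state dynamic program."""
    first = gap_open + gap_extend
    n, m = len(seq_a), len(seq_b)
    NEG = -(10**9)

    @lru_cache(maxsize=None)
    def state(i: int, j: int, kind: str) -> int:
        # best score of a local alignment ending at (i, j) in the given state
        if i < 0 or j < 0:
            return NEG
        if kind == "M":
            prev = max(0, state(i - 1, j - 1, "M"), state(i - 1, j - 1, "X"),
                       state(i - 1, j - 1, "Y"))
            return prev + _sub(seq_a[i], seq_b[j])
        if kind == "X":  # gap in seq_b (consumes seq_a)
            return max(state(i - 1, j, "M") - first, state(i - 1, j, "X") - gap_extend)
        # gap in seq_a (consumes seq_b)
        return max(state(i, j - 1, "M") - first, state(i, j - 1, "Y") - gap_extend)

    best = 0
    for i in range(n):
        for j in range(m):
            best = max(best, state(i, j, "M"))
    state.cache_clear()
    return best


def sw_enumerate_paths(seq_a: str, seq_b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Truly exhaustive enumeration of every local alignment path.

    Exponential; only for validating :func:`sw_oracle` on tiny strings."""
    first = gap_open + gap_extend
    best = 0

    def extend(i: int, j: int, score: int, prev: str) -> None:
        nonlocal best
        best = max(best, score)
        if i < len(seq_a) and j < len(seq_b):
            extend(i + 1, j + 1, score + _sub(seq_a[i], seq_b[j]), "M")
        if i < len(seq_a) and prev != "start":
            cost = gap_extend if prev == "X" else first
            extend(i + 1, j, score - cost, "X")
        if j < len(seq_b) and prev not in ("start", "X"):
            cost = gap_extend if prev == "Y" else first
            extend(i, j + 1, score - cost, "Y")

    for i in range(len(seq_a)):
        for j in range(len(seq_b)):
            extend(i + 1, j + 1, _sub(seq_a[i], seq_b[j]), "M")
    return best


def betweenness_oracle(graph: nx.Graph) -> dict:
    """Normalised betweenness by explicit shortest-path enumeration."""
    nodes = list(graph.nodes)
    n = len(nodes)
    counts = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            counts[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: (c / norm if norm else 0.0) for v, c in counts.items()}
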