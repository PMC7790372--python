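"""Structure-similarity analyses from a precomputed pairwise Z-score matrix.

A symmetric matrix of structural similarity Z-scores (as produced by
distance-matrix comparison servers) drives two views of the data:

* an average-linkage dendrogram on distances ``d = Z_max - Z`` (the maximum
  off-diagonal entry), exported as a newick string, and
* threshold networks with an edge wherever ``Z > z_min`` (strict
  inequality), plus a scan for the smallest integer threshold at which the
  network separates into at least two non-trivial components.

Structural alignment itself is out of scope: the matrix is an input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform


@dataclass
class ZScoreMatrix:
    """Symmetric non-negative structure-similarity matrix.

    The diagonal holds self-similarity and is ignored in all analyses.
    """

    ids: list[str]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.ids)
        if self.Z.shape != (n, n):
            raise ValueError("Z must be square and match ids")
        if not np.allclose(self.Z, self.Z.T, atol=1e-6):
            raise ValueError("Z-score matrix must be symmetric (within 1e-6)")
        off = ~np.eye(n, dtype=bool)
        if n > 1 and (self.Z[off] < 0).any():
            raise ValueError("off-diagonal Z-scores must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def max_offdiag(self) -> float:
        off = ~np.eye(self.n, dtype=bool)
        return float(self.Z[off].max())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ZScoreMatrix":
        frame = pd.read_csv(path, index_col=0)
        ids = [str(c) for c in frame.columns]
        return cls(ids=ids, Z=frame.to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.Z, index=self.ids, columns=self.ids).to_csv(path)


def _distance_condensed(zmatrix: ZScoreMatrix) -> np.ndarray:
    d = zmatrix.max_offdiag() - zmatrix.Z
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    # enforce exact symmetry for squareform after float noise
    d = (d + d.T) / 2.0
    return squareform(d, checks=False)


def _linkage(zmatrix: ZScoreMatrix) -> np.ndarray:
    if zmatrix.n < 2:
        raise ValueError("need at least 2 structures")
    return linkage(_distance_condensed(zmatrix), method="average")


def build_dendrogram(zmatrix: ZScoreMatrix) -> str:
    """Average-linkage dendrogram as a newick string.

    Distances are ``Z_max - Z``; leaf labels are structure ids; branch
    lengths come from the merge heights (ultrametric: a node sits at half
    its merge distance).
    """
    tree = to_tree(_linkage(zmatrix))
    ids = zmatrix.ids

    def newick(node, parent_height: float) -> str:
        height = node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{length:.6g}"

    root_height = tree.dist / 2.0
    left = newick(tree.left, root_height)
    right = newick(tree.right, root_height)
    return f"({left},{right});"


def cut_dendrogram(zmatrix: ZScoreMatrix, k: int) -> dict[str, int]:
    """Flat clustering from cutting the dendrogram into ``k`` clusters."""
    labels = fcluster(_linkage(zmatrix), t=k, criterion="maxclust")
    return dict(zip(zmatrix.ids, (int(c) for c in labels)))


def threshold_network(zmatrix: ZScoreMatrix, z_min: float) -> nx.Graph:
    """Graph with an edge (i, j) iff Z_ij > z_min (no self-edges)."""
    if z_min < 0:
        raise ValueError("z_min must be >= 0")
    graph = nx.Graph()
    graph.add_nodes_from(zmatrix.ids)
    n = zmatrix.n
    for i in range(n):
        for j in range(i + 1, n):
            if zmatrix.Z[i, j] > z_min:
                graph.add_edge(zmatrix.ids[i], zmatrix.ids[j], zscore=float(zmatrix.Z[i, j]))
    return graph


def separation_threshold(
    zmatrix: ZScoreMatrix, min_component_size: int = 3
) -> int | None:
    """Smallest integer z at which the threshold network separates.

    Separation means >= 2 connected components each of size >=
    ``min_component_size`` (stripping singletons off a hairball does not
    count).  Scans integer z from 0 up to ceil(Z_max); returns None when no
    threshold qualifies.
    """
    if min_component_size < 2:
        raise ValueError("min_component_size must be >= 2")
    z_top = int(np.ceil(zmatrix.max_offdiag()))
    for z in range(0, z_top + 1):
        graph = threshold_network(zmatrix, z)
        big = [c for c in nx.connected_components(graph) if len(c) >= min_component_size]
        if len(big) >= 2:
            return z
    return None
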