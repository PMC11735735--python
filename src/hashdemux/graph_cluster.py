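"""Shared-nearest-neighbor graph construction and Louvain clustering.

Cells are clustered directly in the M-dimensional normalized tag space (M is
the number of tags, small enough that no dimensionality reduction is needed).
For each cell the k nearest neighbors by Euclidean distance are found (the
cell itself is included in its own neighborhood, giving sets of size k + 1);
the SNN edge weight between two cells is the Jaccard overlap of their
neighborhoods, and edges with weight <= prune_threshold are dropped. The
resulting weighted graph is partitioned by the Louvain method at a given
resolution, maximizing Q = sum_c [ e_c/m - resolution * (d_c / 2m)^2 ].
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse
from sklearn.neighbors import NearestNeighbors

from .normalization import NormalizedTagMatrix

DEFAULT_PRUNE = 1 / 15


class ParameterError(ValueError):
    pass


@dataclass
class SNNGraph:
    """Undirected SNN graph: edges weighted by Jaccard neighborhood overlap."""

    n_cells: int
    edges: np.ndarray          # (E, 2) int array of cell index pairs, i < j
    weights: np.ndarray        # (E,) floats in (0, 1]
    k: int
    prune_threshold: float = DEFAULT_PRUNE

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(self.n_cells, self.edges.tolist())
        g.es["weight"] = self.weights.tolist()
        return g

    def write_edge_list(self, path) -> None:
        """Dump edges as TSV (debugging aid): columns i, j, weight."""
        with open(path, "w") as fh:
            fh.write("cell_i\tcell_j\tweight\n")
            for (i, j), w in zip(self.edges, self.weights):
                fh.write(f"{i}\t{j}\t{w:.10g}\n")


@dataclass
class ClusterAssignment:
    """Per-cell cluster ids (dense, 0..C-1) plus the parameters that made them."""

    cluster_id: np.ndarray
    resolution: float
    k: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) + 1 if self.cluster_id.size else 0


def build_snn(
    N: NormalizedTagMatrix, k: int, prune_threshold: float = DEFAULT_PRUNE
) -> SNNGraph:
    """Build the shared-nearest-neighbor graph over cells.

    Parameters
    ----------
    N
        Normalized tag matrix (tags x cells); cells are the graph vertices.
    k
        Neighborhood size (excluding self); must satisfy ``k < n_cells``.
    prune_threshold
        Edges with Jaccard weight <= this value are removed (default 1/15).
    """
    n_cells = N.n_cells
    if k >= n_cells:
        raise ParameterError(f"k={k} must be smaller than the number of cells ({n_cells})")
    X = np.ascontiguousarray(N.values.T)  # cells x tags
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    # guarantee self-inclusion (exact duplicates can displace the query point)
    rows = np.arange(n_cells)
    has_self = (idx == rows[:, None]).any(axis=1)
    if not has_self.all():
        idx[~has_self, -1] = rows[~has_self]

    indicator = scipy.sparse.csr_matrix(
        (
            np.ones(idx.size, dtype=np.float64),
            (np.repeat(rows, k + 1), idx.ravel()),
        ),
        shape=(n_cells, n_cells),
    )
    shared = indicator @ indicator.T  # |A ∩ B|
    shared = scipy.sparse.triu(shared, k=1).tocoo()
    inter = shared.data
    union = 2.0 * (k + 1) - inter
    jaccard = inter / union
    keep = jaccard > prune_threshold
    edges = np.column_stack([shared.row[keep], shared.col[keep]]).astype(np.int64)
    return SNNGraph(n_cells, edges, jaccard[keep], k, prune_threshold)


def louvain(graph: SNNGraph, resolution: float = 1.0, seed: int = 0) -> ClusterAssignment:
    """Partition an SNN graph with Louvain community detection.

    Deterministic for a fixed seed; a graph with no edges yields one cluster
    per cell. Cluster ids are relabeled to be dense, ordered by first
    occurrence along the cell index.
    """
    if graph.n_cells == 0:
        raise ParameterError("empty graph")
    g = graph.to_igraph()
    ig.set_random_number_generator(random.Random(seed))
    membership = np.asarray(
        g.community_multilevel(
            weights="weight" if graph.edges.size else None, resolution=resolution
        ).membership
    )
    # dense relabel by first occurrence
    _, first_pos = np.unique(membership, return_index=True)
    order = membership[np.sort(first_pos)]
    remap = {old: new for new, old in enumerate(order)}
    dense = np.array([remap[c] for c in membership], dtype=np.int64)
    return ClusterAssignment(dense, resolution=resolution, k=graph.k, seed=seed)
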