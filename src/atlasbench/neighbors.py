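"""k-nearest-neighbor plumbing shared by the metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["NeighborGraph", "knn_graph"]


@dataclass
class NeighborGraph:
    """Per-row neighbor indices and distances, self excluded, sorted ascending."""

    indices: np.ndarray
    distances: np.ndarray
    k: int

    def adjacency(self, n: int | None = None) -> sparse.csr_matrix:
        """Symmetric unweighted adjacency matrix of the kNN graph."""
        n = n if n is not None else self.indices.shape[0]
        rows = np.repeat(np.arange(self.indices.shape[0]), self.k)
        a = sparse.csr_matrix(
            (np.ones(rows.size), (rows, self.indices.ravel())), shape=(n, n)
        )
        a = a.maximum(a.T)
        return a


def knn_graph(coords: np.ndarray, k: int) -> NeighborGraph:
    """k nearest neighbors of each row among all rows (self excluded)."""
    from sklearn.neighbors import NearestNeighbors

    n = coords.shape[0]
    k = min(k, n - 1)
    if k < 1:
        raise ValueError("need at least 2 points for a neighbor graph")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop self (first column when distances start at 0; guard against ties)
    out_idx = np.empty((n, k), dtype=np.int64)
    out_dist = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        cols = idx[i] != i
        if cols.sum() == k + 1:  # self not returned (duplicate points)
            cols[-1] = False
        out_idx[i] = idx[i][cols][:k]
        out_dist[i] = dist[i][cols][:k]
    return NeighborGraph(indices=out_idx, distances=out_dist, k=k)
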