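"""Biology-conservation metrics.

These ask whether cell labels remain separated and internal structure is
preserved after integration: batch-balanced NMI against a Leiden resolution
sweep, isolated-label silhouette and F1, per-label graph connectivity, and
the local-density-factor difference between pre- and post-integration
embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph

from ..core_data import JointEmbedding
from ..neighbors import knn_graph
from .config import MetricConfig, MetricScore

__all__ = [
    "leiden_sweep",
    "cluster_sweep",
    "bnmi",
    "balanced_nmi",
    "isolated_label_scores",
    "graph_connectivity",
    "ldf_diff",
]


# ---------------------------------------------------------------------------
# Leiden resolution sweep


def leiden_sweep(
    coords: np.ndarray, cfg: MetricConfig | None = None
) -> dict[float, np.ndarray]:
    """Leiden clusterings of the kNN graph at every configured resolution."""
    import igraph as ig
    import leidenalg

    cfg = cfg or MetricConfig()
    graph = knn_graph(np.asarray(coords, float), cfg.knn_k_graph)
    adj = graph.adjacency().tocoo()
    mask = adj.row < adj.col
    edges = list(zip(adj.row[mask].tolist(), adj.col[mask].tolist()))
    g = ig.Graph(n=coords.shape[0], edges=edges)
    out = {}
    for res in cfg.leiden_resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=cfg.seed,
            n_iterations=2,
        )
        out[res] = np.asarray(part.membership, dtype=int)
    return out


@dataclass
class SweepResult:
    clusters: np.ndarray
    objective: float
    resolution: float
    all_clusterings: dict[float, np.ndarray]


def cluster_sweep(
    coords: np.ndarray,
    objective,
    cfg: MetricConfig | None = None,
    clusterings: dict[float, np.ndarray] | None = None,
) -> SweepResult:
    """Pick the Leiden resolution maximizing ``objective(clusters)``.

    Ties resolve to the lowest resolution. A precomputed ``clusterings`` dict
    (from :func:`leiden_sweep`) may be passed to share the sweep between
    metrics.
    """
    cfg = cfg or MetricConfig()
    if clusterings is None:
        clusterings = leiden_sweep(coords, cfg)
    best_res, best_val, best_clusters = None, -np.inf, None
    for res in sorted(clusterings):
        val = float(objective(clusterings[res]))
        if val > best_val + 1e-15:
            best_res, best_val, best_clusters = res, val, clusterings[res]
    return SweepResult(best_clusters, best_val, best_res, clusterings)


# ---------------------------------------------------------------------------
# Batch-balanced NMI


def balanced_nmi(
    clusters: np.ndarray, labels: np.ndarray, batch: np.ndarray
) -> float:
    """NMI of a batch-balanced cluster x label contingency table.

    Each cell is weighted ``1 / (B * n_batch(cell))`` so every batch
    contributes equal total weight; mutual information and entropies are
    computed from the weighted table and normalised by the arithmetic mean
    of the entropies. Reduces to plain NMI when batches are equal-sized.
    """
    clusters = np.asarray(clusters)
    labels = np.asarray(labels)
    batch = np.asarray(batch)
    cu, ci = np.unique(clusters, return_inverse=True)
    lu, li = np.unique(labels, return_inverse=True)
    if cu.size < 2 or lu.size < 2:
        return 0.0
    bu, bi = np.unique(batch, return_inverse=True)
    sizes = np.bincount(bi)
    w = 1.0 / (bu.size * sizes[bi])
    table = np.zeros((cu.size, lu.size))
    np.add.at(table, (ci, li), w)
    p = table / table.sum()
    pc, pl = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    mi = (p[nz] * np.log(p[nz] / np.outer(pc, pl)[nz])).sum()
    hc = -(pc[pc > 0] * np.log(pc[pc > 0])).sum()
    hl = -(pl[pl > 0] * np.log(pl[pl > 0])).sum()
    denom = (hc + hl) / 2.0
    return float(mi / denom) if denom > 0 else 0.0


def bnmi(
    coords: np.ndarray,
    labels: np.ndarray,
    batch: np.ndarray,
    cfg: MetricConfig | None = None,
    clusterings: dict[float, np.ndarray] | None = None,
) -> MetricScore:
    """Best batch-balanced NMI over the Leiden resolution sweep."""
    sweep = cluster_sweep(
        coords,
        lambda c: balanced_nmi(c, labels, batch),
        cfg,
        clusterings=clusterings,
    )
    return MetricScore(
        "bnmi",
        "bio",
        float(np.clip(sweep.objective, 0.0, 1.0)),
        n_cells_used=len(labels),
        notes=f"resolution={sweep.resolution}",
    )


# ---------------------------------------------------------------------------
# Isolated labels


def _isolated_labels(labels: np.ndarray, batch: np.ndarray) -> list:
    """Labels present in the minimum number of batches."""
    labs = np.unique(labels)
    n_batches = {
        lab: np.unique(batch[labels == lab]).size for lab in labs
    }
    lo = min(n_batches.values())
    if lo == np.unique(batch).size:
        warnings.warn(
            "every label occurs in every batch; treating all labels as isolated"
        )
    return [lab for lab in labs if n_batches[lab] == lo]


def isolated_label_scores(
    coords: np.ndarray,
    labels: np.ndarray,
    batch: np.ndarray,
    cfg: MetricConfig | None = None,
    clusterings: dict[float, np.ndarray] | None = None,
) -> tuple[MetricScore, MetricScore]:
    """Silhouette and cluster-F1 scores for the isolated labels.

    Isolated labels are those shared by the fewest batches — populations the
    integration cannot align across batches and may therefore destroy. The
    ASW variant rescales each isolated label's binary silhouette to [0, 1];
    the F1 variant takes, per isolated label, the best F1 between membership
    in any Leiden cluster (across the resolution sweep) and membership in the
    label.
    """
    from sklearn.metrics import silhouette_samples

    cfg = cfg or MetricConfig()
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    batch = np.asarray(batch)
    isolated = _isolated_labels(labels, batch)

    asw_vals = []
    for lab in isolated:
        mask = labels == lab
        if mask.all():
            asw_vals.append(1.0)
            continue
        sil = silhouette_samples(coords, mask.astype(int))
        asw_vals.append(float(((sil[mask] + 1.0) / 2.0).mean()))
    asw = MetricScore(
        "isolated_label_asw", "bio", float(np.mean(asw_vals)),
        n_cells_used=labels.size, notes=f"isolated={isolated}"
    )

    if clusterings is None:
        clusterings = leiden_sweep(coords, cfg)
    f1_vals = []
    for lab in isolated:
        truth = labels == lab
        best = 0.0
        for clusters in clusterings.values():
            for c in np.unique(clusters):
                pred = clusters == c
                tp = (pred & truth).sum()
                if tp == 0:
                    continue
                f1 = 2 * tp / (pred.sum() + truth.sum())
                best = max(best, f1)
        f1_vals.append(best)
    f1 = MetricScore(
        "isolated_label_f1", "bio", float(np.mean(f1_vals)),
        n_cells_used=labels.size, notes=f"isolated={isolated}"
    )
    return asw, f1


# ---------------------------------------------------------------------------
# Graph connectivity


def graph_connectivity(
    coords: np.ndarray, labels: np.ndarray, cfg: MetricConfig | None = None
) -> MetricScore:
    """Mean, over labels, of the largest-connected-component fraction of the
    label-restricted kNN subgraph. A well-integrated label is one whose cells
    form a single connected neighborhood structure."""
    cfg = cfg or MetricConfig()
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    adj = knn_graph(coords, cfg.knn_k_graph).adjacency()
    vals = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size == 1:
            vals.append(1.0)
            continue
        sub = adj[np.ix_(idx, idx)]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        vals.append(largest / idx.size)
    return MetricScore(
        "graph_connectivity", "bio", float(np.mean(vals)), n_cells_used=labels.size
    )


# ---------------------------------------------------------------------------
# Local density factor difference


def _local_density_factor(
    coords: np.ndarray, k: int, eps: float = 1e-12
) -> np.ndarray:
    """Density of each cell relative to the mean density of its k neighbors.

    Density is the inverse mean distance to the k nearest neighbors; the
    factor is the cell's density divided by its neighbors' average density,
    so values above 1 mark cells denser than their surroundings.
    """
    n = coords.shape[0]
    k = min(k, n - 1)
    graph = knn_graph(coords, k)
    density = 1.0 / (graph.distances.mean(axis=1) + eps)
    neighbor_density = density[graph.indices].mean(axis=1)
    return density / np.maximum(neighbor_density, eps)


def ldf_diff(
    emb: JointEmbedding,
    batch: np.ndarray,
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Change in local density factor from pre- to post-integration.

    The pre-integration factor is computed within each cell's own batch (the
    only structure that exists before integration); the post factor in the
    full integrated space. The absolute log2 change is capped at
    ``ldf_bound`` to give a per-cell score, and the metric is 1 minus the
    mean. Integration that preserves each batch's internal density structure
    scores near 1.
    """
    cfg = cfg or MetricConfig()
    if emb.pre_integration is None:
        raise ValueError("ldf_diff requires a pre-integration embedding")
    batch = np.asarray(batch)
    coords_post = emb.all_coords
    n = coords_post.shape[0]
    if batch.size != n:
        raise ValueError("batch must cover reference and query cells")

    k = cfg.knn_k_graph
    ldf_pre = np.empty(n)
    for b in np.unique(batch):
        idx = np.flatnonzero(batch == b)
        kb = min(k, idx.size - 1)
        if kb < 1:
            ldf_pre[idx] = 1.0
            continue
        ldf_pre[idx] = _local_density_factor(emb.pre_integration[idx], kb)
    ldf_post = _local_density_factor(coords_post, min(k, n - 1))

    diff = np.abs(np.log2(np.maximum(ldf_post, 1e-12))
                  - np.log2(np.maximum(ldf_pre, 1e-12)))
    cell_score = np.minimum(diff, cfg.ldf_bound) / cfg.ldf_bound
    return MetricScore(
        "ldf_diff", "bio", float(1.0 - cell_score.mean()), n_cells_used=n
    )
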