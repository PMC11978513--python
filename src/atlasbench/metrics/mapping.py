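"""Mapping-quality metrics: Mahalanobis cell/label distances and kNN
correlation.

These judge how faithfully the query has been merged into the reference
space: mapped query cells of a shared label should land inside that label's
reference distribution, label centroids should coincide, and each query
cell's local neighborhood geometry should survive the mapping.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import spearmanr

from ..core_data import JointEmbedding, SplitDataset
from .config import MetricConfig, MetricScore
from ._mahalanobis import fit_label_gaussians

__all__ = ["cell_distance", "label_distance", "knn_correlation"]


def _shared_labels(ref_labels, query_labels, unseen_labels):
    ref_set = set(np.unique(ref_labels))
    query_set = set(np.unique(query_labels))
    unseen = set(unseen_labels)
    stray = query_set - ref_set - unseen
    if stray:
        warnings.warn(
            f"query labels absent from reference and not declared unseen; "
            f"excluded: {sorted(stray)}"
        )
    shared = (query_set & ref_set) - unseen
    return shared


def cell_distance(
    emb: JointEmbedding,
    ref_labels,
    query_labels,
    unseen_labels=(),
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Fraction of mapped query cells inside their label's reference boundary.

    For each shared label a Gaussian is fit to the reference cells and the
    boundary set at the configured quantile (default 90th) of the reference
    cells' own Mahalanobis distances; a query cell farther than its label's
    boundary (strictly) counts as outside. Unseen-label query cells are
    excluded. The score is 1 minus the proportion outside, so a query drawn
    from the reference distribution itself scores about 0.90.
    """
    cfg = cfg or MetricConfig()
    ref_labels = np.asarray(ref_labels, dtype=object)
    query_labels = np.asarray(query_labels, dtype=object)
    shared = _shared_labels(ref_labels, query_labels, unseen_labels)
    if not shared:
        raise ValueError("no labels shared between reference and query")
    gaussians = fit_label_gaussians(
        emb.ref_coords, ref_labels, cfg.cov_shrinkage_eps, cfg.cell_dist_quantile
    )
    n_total, n_outside = 0, 0
    for lab in shared:
        q = emb.query_coords[query_labels == lab]
        d = gaussians[lab].distance(q)
        n_total += q.shape[0]
        n_outside += int((d > gaussians[lab].boundary).sum())
    return MetricScore(
        "cell_distance", "mapping", 1.0 - n_outside / n_total, n_cells_used=n_total
    )


def label_distance(
    emb: JointEmbedding,
    ref_labels,
    query_labels,
    unseen_labels=(),
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Centroid agreement between query and reference per shared label.

    Per eligible label (at least ``label_min_query_cells`` query cells and
    present in the reference): the Mahalanobis distance D (reference label
    covariance) between query and reference centroids, scaled by the maximum
    distance M of the label's query cells to their own centroid and capped at
    1; the label scores 1 - min(D/M, 1) and the metric is the mean across
    labels.
    """
    cfg = cfg or MetricConfig()
    ref_labels = np.asarray(ref_labels, dtype=object)
    query_labels = np.asarray(query_labels, dtype=object)
    shared = _shared_labels(ref_labels, query_labels, unseen_labels)
    gaussians = fit_label_gaussians(
        emb.ref_coords, ref_labels, cfg.cov_shrinkage_eps, cfg.cell_dist_quantile
    )
    scores = []
    for lab in sorted(shared, key=str):
        q = emb.query_coords[query_labels == lab]
        if q.shape[0] < cfg.label_min_query_cells:
            continue
        g = gaussians[lab]
        centroid = q.mean(axis=0)
        dmat = g.precision
        diff = centroid - g.mean
        dist = float(np.sqrt(max(diff @ dmat @ diff, 0.0)))
        rel = q - centroid
        m = float(np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", rel, dmat, rel), 0.0
        )).max())
        if m == 0.0:
            scores.append(1.0 if dist == 0.0 else 0.0)
        else:
            scores.append(1.0 - min(dist / m, 1.0))
    if not scores:
        raise ValueError(
            "no shared label with enough query cells for label_distance"
        )
    return MetricScore(
        "label_distance", "mapping", float(np.mean(scores)), n_cells_used=len(scores)
    )


def knn_correlation(
    ds: SplitDataset,
    emb: JointEmbedding,
    features=None,
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Preservation of query-cell neighborhood geometry through the mapping.

    Per query batch, a PCA is computed from that batch's counts alone
    (log1p counts-per-10k on the selected features); for each cell the
    Spearman correlation between its distances to its 100 batch-PCA nearest
    neighbors and the distances to the same cells in the joint embedding is
    rescaled to [0, 1] (undefined correlations score 0). Cell scores are
    averaged within, then across, query batches. Optional metric: excluded
    from default category means.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    cfg = cfg or MetricConfig()
    query = ds.query
    if features is not None:
        query = query.subset_features(np.isin(query.feature_ids, features))
    batch_scores = []
    for b in np.unique(query.batch):
        mask = query.batch == b
        counts = query.subset_cells(mask).dense_counts()
        coords_joint = emb.query_coords[mask]
        n = counts.shape[0]
        k = cfg.knn_corr_k
        if n <= k + 1:
            k = max(n - 2, 1)
            warnings.warn(f"batch {b!r}: knn_corr_k reduced to {k}")
        totals = counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        x = np.log1p(counts / totals * 1e4)
        n_pc = min(30, n - 1, x.shape[1])
        pcs = PCA(n_components=n_pc, svd_solver="full").fit_transform(x)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
        dist, idx = nn.kneighbors(pcs)
        cell_scores = np.empty(n)
        for i in range(n):
            neigh = idx[i][1:]
            d_pca = dist[i][1:]
            d_joint = np.linalg.norm(
                coords_joint[neigh] - coords_joint[i], axis=1
            )
            if np.ptp(d_joint) == 0 or np.ptp(d_pca) == 0:
                cell_scores[i] = 0.0
                continue
            rho = spearmanr(d_pca, d_joint).statistic
            cell_scores[i] = 0.0 if not np.isfinite(rho) else (rho + 1.0) / 2.0
        batch_scores.append(cell_scores.mean())
    return MetricScore(
        "knn_correlation", "mapping", float(np.mean(batch_scores)),
        n_cells_used=query.n_cells
    )
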