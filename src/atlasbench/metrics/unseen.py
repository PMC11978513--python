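"""Unseen-population metrics.

Unseen populations are query labels deliberately removed from the reference.
A good mapping keeps them separable: far from every reference label's
distribution (cell/label distance variants), concentrated in neighborhoods
that are significantly enriched for query cells (the Milo-style score), and
classified with low confidence (the uncertainty variant).
"""

from __future__ import annotations

import warnings

import numpy as np

from ..core_data import JointEmbedding
from ..transfer import TransferResult
from .config import MetricConfig, MetricScore
from ._mahalanobis import fit_label_gaussians

__all__ = [
    "unseen_uncertainty",
    "unseen_cell_distance",
    "unseen_label_distance",
    "milo_score",
]


def unseen_uncertainty(tr: TransferResult, unseen_mask) -> MetricScore:
    """1 minus the mean assigned-class probability over unseen query cells.

    A classifier forced to label cells whose true population it never saw
    should at least be uncertain about them. Optional metric: excluded from
    default category means.
    """
    unseen_mask = np.asarray(unseen_mask, dtype=bool)
    if not unseen_mask.any():
        raise ValueError("no unseen query cells")
    top = tr.probabilities[unseen_mask].max(axis=1)
    return MetricScore(
        "unseen_uncertainty", "unseen", float(1.0 - top.mean()),
        n_cells_used=int(unseen_mask.sum())
    )


def unseen_cell_distance(
    emb: JointEmbedding,
    ref_labels,
    query_labels,
    unseen_labels,
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Proportion of unseen query cells outside their nearest reference label.

    Each unseen cell's nearest reference label is the one with the smallest
    Mahalanobis distance; the cell counts as outside if that distance
    (strictly) exceeds the label's quantile boundary. Higher separation gives
    a higher score.
    """
    cfg = cfg or MetricConfig()
    ref_labels = np.asarray(ref_labels, dtype=object)
    query_labels = np.asarray(query_labels, dtype=object)
    mask = np.isin(query_labels, list(unseen_labels))
    if not mask.any():
        raise ValueError("no unseen query cells")
    gaussians = fit_label_gaussians(
        emb.ref_coords, ref_labels, cfg.cov_shrinkage_eps, cfg.cell_dist_quantile
    )
    cells = emb.query_coords[mask]
    labs = sorted(gaussians, key=str)
    dists = np.stack([gaussians[l].distance(cells) for l in labs], axis=1)
    bounds = np.array([gaussians[l].boundary for l in labs])
    nearest = np.argmin(dists, axis=1)
    outside = dists[np.arange(cells.shape[0]), nearest] > bounds[nearest]
    return MetricScore(
        "unseen_cell_distance", "unseen", float(outside.mean()),
        n_cells_used=int(mask.sum())
    )


def unseen_label_distance(
    emb: JointEmbedding,
    ref_labels,
    query_labels,
    unseen_labels,
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Centroid separation of each unseen label from its nearest reference label.

    Per unseen label with at least ``label_min_query_cells`` query cells:
    D is the Mahalanobis distance from its centroid to the nearest reference
    label centroid (that label's covariance), M the maximum distance of the
    unseen label's own cells to their centroid under the same covariance;
    the label scores min(D/M, 1). Labels below the size threshold are
    skipped; if all are skipped the metric is 0.
    """
    cfg = cfg or MetricConfig()
    ref_labels = np.asarray(ref_labels, dtype=object)
    query_labels = np.asarray(query_labels, dtype=object)
    gaussians = fit_label_gaussians(
        emb.ref_coords, ref_labels, cfg.cov_shrinkage_eps, cfg.cell_dist_quantile
    )
    scores = []
    skipped = []
    for lab in sorted(set(unseen_labels), key=str):
        cells = emb.query_coords[query_labels == lab]
        if cells.shape[0] < cfg.label_min_query_cells:
            skipped.append(lab)
            continue
        centroid = cells.mean(axis=0)
        best_d, best_g = np.inf, None
        for g in gaussians.values():
            d = float(g.distance(centroid[None, :])[0])
            if d < best_d:
                best_d, best_g = d, g
        rel = cells - centroid
        m = float(np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", rel, best_g.precision, rel), 0.0
        )).max())
        if m == 0.0:
            scores.append(1.0 if best_d > 0 else 0.0)
        else:
            scores.append(min(best_d / m, 1.0))
    if not scores:
        warnings.warn("all unseen labels below the query-cell threshold; score 0")
        return MetricScore("unseen_label_distance", "unseen", 0.0,
                           notes=f"all skipped: {skipped}")
    notes = f"skipped: {skipped}" if skipped else ""
    return MetricScore(
        "unseen_label_distance", "unseen", float(np.mean(scores)),
        n_cells_used=len(scores), notes=notes
    )


# ---------------------------------------------------------------------------
# Milo-style neighborhood differential abundance


def _common_dispersion(
    counts: np.ndarray, is_query_batch: np.ndarray, batch_sizes: np.ndarray
) -> float:
    """Moment estimate of a shared NB dispersion across all neighborhoods.

    Under the null model (intercept + query indicator + log batch-size
    offset) the Poisson MLE has the closed form mu_b = N_b * T_arm / N_arm
    per arm; the dispersion alpha solves var = mu + alpha mu^2 by pooling
    Pearson-style residuals over every neighborhood and batch.
    """
    mu = np.zeros_like(counts, dtype=float)
    for arm in (is_query_batch, ~is_query_batch):
        n_arm = batch_sizes[arm].sum()
        t_arm = counts[:, arm].sum(axis=1, keepdims=True)
        mu[:, arm] = t_arm * batch_sizes[arm][None, :] / n_arm
    resid2 = (counts - mu) ** 2 - mu
    denom = (mu**2).sum()
    if denom == 0:
        return 0.01
    return float(np.clip(resid2.sum() / denom, 0.01, 10.0))


def _nb_query_pvalue(
    counts: np.ndarray,
    is_query_batch: np.ndarray,
    batch_sizes: np.ndarray,
    alpha: float,
) -> float:
    """One-sided p-value for query enrichment of one neighborhood.

    Negative-binomial regression of per-batch neighborhood counts on the
    batch's query indicator with a log batch-size offset; Wald test of a
    positive query coefficient. Falls back to an exact one-sided binomial
    test of query membership against the overall query fraction when the
    regression is separated (one arm all zero) or cannot be fit.
    """
    import statsmodels.api as sm
    from scipy.stats import binomtest, norm

    try:
        if counts[is_query_batch].sum() == 0 or counts[~is_query_batch].sum() == 0:
            raise ValueError("separated counts")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x = np.column_stack([np.ones(counts.size), is_query_batch.astype(float)])
            res = sm.GLM(
                counts,
                x,
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(batch_sizes),
            ).fit(maxiter=50)
        coef, se = res.params[1], res.bse[1]
        if not np.isfinite(coef) or not np.isfinite(se) or se == 0 or se > 50:
            raise ValueError("degenerate fit")
        return float(norm.sf(coef / se))
    except Exception:
        n = int(counts.sum())
        q = int(counts[is_query_batch].sum())
        frac = batch_sizes[is_query_batch].sum() / batch_sizes.sum()
        return float(binomtest(q, n, frac, alternative="greater").pvalue)


def milo_score(
    emb: JointEmbedding,
    batch,
    is_query,
    labels,
    unseen_labels,
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Proportion of each unseen label's neighborhoods enriched for the query.

    Index cells are subsampled (20,000 or 10% of cells, whichever is higher)
    from the joint embedding; each index cell's neighborhood is itself plus
    its k nearest neighbors with k = min(5 x n_batches, 200). Neighborhood
    query-association is tested per batch-level count (negative-binomial
    regression with binomial fallback), p-values are Benjamini-Hochberg
    adjusted across neighborhoods, and each neighborhood is attributed to the
    majority label among its members (ties to the index cell's label). Each
    unseen label scores the proportion of its neighborhoods significant at
    the configured FDR (0 if it owns no neighborhood); the metric is the mean
    over unseen labels.

    ``batch``, ``is_query`` and ``labels`` cover all cells, reference rows
    first then query rows, matching ``emb.all_coords``.
    """
    from statsmodels.stats.multitest import multipletests

    from ..neighbors import knn_graph

    cfg = cfg or MetricConfig()
    batch = np.asarray(batch, dtype=object)
    is_query = np.asarray(is_query, dtype=bool)
    labels = np.asarray(labels, dtype=object)
    coords = emb.all_coords
    n = coords.shape[0]
    if not (batch.size == is_query.size == labels.size == n):
        raise ValueError("batch/is_query/labels must cover all cells")
    batch_names = np.unique(batch)
    if batch_names.size < 2:
        raise ValueError("milo_score requires >= 2 batches")

    rng = np.random.default_rng(cfg.seed)
    n_index = min(n, cfg.milo_subset(n))
    index_cells = (
        np.arange(n) if n_index == n
        else np.sort(rng.choice(n, size=n_index, replace=False))
    )
    k = min(cfg.milo_k(batch_names.size), n - 1)
    graph = knn_graph(coords, k)

    batch_codes = np.unique(batch, return_inverse=True)[1]
    batch_sizes = np.bincount(batch_codes).astype(float)
    query_batch = np.zeros(batch_names.size, dtype=bool)
    for c in range(batch_names.size):
        query_batch[c] = is_query[batch_codes == c].any()

    count_mat = np.empty((index_cells.size, batch_names.size))
    nbhd_label = np.empty(index_cells.size, dtype=object)
    for j, i in enumerate(index_cells):
        members = np.r_[i, graph.indices[i]]
        count_mat[j] = np.bincount(batch_codes[members], minlength=batch_names.size)
        labs, cnt = np.unique(labels[members], return_counts=True)
        top = cnt.max()
        tied = labs[cnt == top]
        nbhd_label[j] = labels[i] if labels[i] in tied else sorted(tied, key=str)[0]

    alpha = _common_dispersion(count_mat, query_batch, batch_sizes)
    pvals = np.array([
        _nb_query_pvalue(count_mat[j], query_batch, batch_sizes, alpha)
        for j in range(index_cells.size)
    ])

    adj = multipletests(pvals, method="fdr_bh")[1]
    scores = []
    for lab in sorted(set(unseen_labels), key=str):
        mask = nbhd_label == lab
        if not mask.any():
            scores.append(0.0)  # label never dominates a neighborhood
            continue
        scores.append(float((adj[mask] < cfg.milo_fdr).mean()))
    if not scores:
        raise ValueError("no unseen labels supplied")
    return MetricScore(
        "milo", "unseen", float(np.mean(scores)), n_cells_used=index_cells.size
    )
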