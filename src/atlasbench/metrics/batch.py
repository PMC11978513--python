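"""Batch-mixing metrics: LISI variants, batch PCR and the cell-specific
mixing score (CMS).

All LISI modes share one engine: per cell, Gaussian kernel weights over its
nearest neighbors with the bandwidth solved to match a target perplexity
(as in t-SNE's conditional distributions); Simpson's index of the grouping
under those weights; the inverse averaged over cells and rescaled to [0, 1].
Mixing groupings (batch, reference-vs-query origin, query batch) score high
when neighborhoods are mixed; the label grouping (cLISI) scores high when
neighborhoods are pure.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..core_data import JointEmbedding
from ..neighbors import knn_graph
from .config import MetricConfig, MetricScore

__all__ = ["lisi_score", "per_cell_lisi", "batch_pcr", "pcr", "cms_score"]

_LISI_MODES = {
    "ilisi": ("batch", "mixing"),
    "clisi": ("bio", "separation"),
    "mlisi": ("mapping", "mixing"),
    "qlisi": ("mapping", "mixing"),
}


def _perplexity_weights(distances: np.ndarray, perplexity: float) -> np.ndarray:
    """Gaussian weights per row with bandwidth solved to the target perplexity.

    Binary search on the precision beta so that the entropy of the weight
    distribution equals log(perplexity), the standard t-SNE calibration.
    """
    n, k = distances.shape
    target = np.log(perplexity)
    weights = np.empty_like(distances)
    d2 = distances**2
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        row = d2[i] - d2[i].min()
        for _ in range(64):
            w = np.exp(-beta * row)
            s = w.sum()
            p = w / s
            h = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(h - target) < 1e-7:
                break
            if h > target:  # too flat -> increase beta
                lo = beta
                beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        weights[i] = p
    return weights


def per_cell_lisi(
    coords: np.ndarray, grouping: np.ndarray, perplexity: float = 30.0
) -> np.ndarray:
    """Per-cell inverse Simpson's index of ``grouping`` under perplexity weights."""
    coords = np.asarray(coords, dtype=float)
    grouping = np.asarray(grouping)
    n = coords.shape[0]
    k = int(min(3 * perplexity, n - 1))
    if k < 3 * perplexity:
        new_perp = max(k / 3.0, 1.001)
        warnings.warn(
            f"fewer cells than the perplexity window; perplexity reduced to "
            f"{new_perp:.2f}"
        )
        perplexity = new_perp
    graph = knn_graph(coords, k)
    weights = _perplexity_weights(graph.distances, perplexity)
    groups, codes = np.unique(grouping, return_inverse=True)
    neighbor_codes = codes[graph.indices]
    simpson = np.zeros(n)
    for g in range(groups.size):
        pg = np.where(neighbor_codes == g, weights, 0.0).sum(axis=1)
        simpson += pg**2
    return 1.0 / simpson


def lisi_score(
    coords: np.ndarray,
    grouping: np.ndarray,
    mode: str,
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Rescaled mean LISI of ``grouping`` over ``coords``.

    Mixing modes map the mean inverse Simpson's index LISI in [1, G] to
    (LISI - 1)/(G - 1); the separation mode (clisi) to (G - LISI)/(G - 1).
    The caller supplies the cells and grouping appropriate to the mode:
    reference cells with batch (ilisi) or label (clisi), all cells with
    origin (mlisi), query cells with batch (qlisi).
    """
    cfg = cfg or MetricConfig()
    if mode not in _LISI_MODES:
        raise ValueError(f"unknown LISI mode {mode!r}")
    category, kind = _LISI_MODES[mode]
    grouping = np.asarray(grouping)
    groups = np.unique(grouping)
    g = groups.size
    if g < 2:
        if kind == "separation":
            warnings.warn("single group: separation trivially perfect")
            return MetricScore(mode, category, 1.0, n_cells_used=grouping.size,
                               notes="single group")
        raise ValueError(f"{mode} requires >= 2 groups")
    lisi = per_cell_lisi(coords, grouping, cfg.lisi_perplexity).mean()
    if kind == "mixing":
        value = (lisi - 1.0) / (g - 1.0)
    else:
        value = (g - lisi) / (g - 1.0)
    return MetricScore(mode, category, float(np.clip(value, 0.0, 1.0)),
                       n_cells_used=grouping.size)


# ---------------------------------------------------------------------------
# Batch PCR


def pcr(x: np.ndarray, batch: np.ndarray, n_comps: int = 50) -> float:
    """Variance-weighted R-squared of principal components on batch.

    The fraction of embedding variance explained by batch: principal
    components of ``x`` are each regressed on one-hot batch indicators and
    the per-component R-squared values are averaged weighted by component
    variance.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(x, dtype=float)
    batch = np.asarray(batch)
    n, d = x.shape
    n_comps = min(n_comps, d, n - 1)
    pca = PCA(n_components=n_comps, svd_solver="full")
    pcs = pca.fit_transform(x)
    var = pca.explained_variance_
    if var.sum() == 0:
        return 0.0
    # R^2 of a one-hot regression is computable from group means
    r2 = np.empty(n_comps)
    for i in range(n_comps):
        y = pcs[:, i]
        sst = ((y - y.mean()) ** 2).sum()
        if sst == 0:
            r2[i] = 0.0
            continue
        sse = 0.0
        for b in np.unique(batch):
            yb = y[batch == b]
            sse += ((yb - yb.mean()) ** 2).sum()
        r2[i] = 1.0 - sse / sst
    return float((var * r2).sum() / var.sum())


def batch_pcr(
    emb: JointEmbedding,
    batch: np.ndarray,
    n_comps: int = 50,
    cfg: MetricConfig | None = None,
) -> MetricScore:
    """Reduction in batch-explained variance from pre- to post-integration.

    With a pre-integration embedding available the score is
    ``clip((PCR_pre - PCR_post) / PCR_pre, 0, 1)``; without one it falls back
    to ``1 - PCR_post``. ``batch`` holds reference batch labels.
    """
    batch = np.asarray(batch)
    n_ref = emb.ref_coords.shape[0]
    if batch.size != n_ref:
        raise ValueError("batch must align with reference cells")
    post = pcr(emb.ref_coords, batch, n_comps)
    if emb.pre_integration is None:
        return MetricScore("batch_pcr", "batch", 1.0 - post, n_cells_used=n_ref,
                           notes="no pre-integration embedding; 1 - PCR_post")
    pre = pcr(emb.pre_integration[:n_ref], batch, n_comps)
    if pre == 0:
        warnings.warn("pre-integration PCR is 0: nothing to remove; score 1")
        return MetricScore("batch_pcr", "batch", 1.0, n_cells_used=n_ref,
                           notes="PCR_pre = 0")
    value = float(np.clip((pre - post) / pre, 0.0, 1.0))
    return MetricScore("batch_pcr", "batch", value, n_cells_used=n_ref)


# ---------------------------------------------------------------------------
# CMS


def cms_score(
    coords: np.ndarray, batch: np.ndarray, cfg: MetricConfig | None = None
) -> MetricScore:
    """Cell-specific mixing score.

    Per cell, the distances to its k nearest neighbors are grouped by the
    neighbors' batch and compared with an Anderson-Darling k-sample test;
    under good mixing the distance distributions are exchangeable across
    batches and p-values are uniform. The score is 1 minus the proportion of
    cells with p below ``cms_alpha``. Batch groups with fewer than 5
    neighbors are dropped; cells left with fewer than 2 groups get p = 0.
    """
    from scipy.stats import anderson_ksamp

    cfg = cfg or MetricConfig()
    coords = np.asarray(coords, dtype=float)
    batch = np.asarray(batch)
    n = coords.shape[0]
    if np.unique(batch).size < 2:
        raise ValueError("CMS requires >= 2 batches")
    k = cfg.cms_k
    if k >= n:
        warnings.warn(f"cms_k={k} >= n={n}; reduced to {n - 1}")
        k = n - 1
    graph = knn_graph(coords, k)
    codes = np.unique(batch, return_inverse=True)[1]
    neighbor_codes = codes[graph.indices]
    n_sig = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns when p is capped
        for i in range(n):
            groups = [
                graph.distances[i][neighbor_codes[i] == g]
                for g in np.unique(neighbor_codes[i])
            ]
            groups = [g for g in groups if g.size >= 5]
            if len(groups) < 2:
                p = 0.0
            else:
                try:
                    p = float(anderson_ksamp(groups).significance_level)
                except ValueError:  # all values identical
                    p = 1.0
            if p < cfg.cms_alpha:
                n_sig += 1
    return MetricScore("cms", "batch", 1.0 - n_sig / n, n_cells_used=n)
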