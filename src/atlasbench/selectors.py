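"""Feature selectors driving the benchmark pipeline.

Simple controls (all features, random sets), raw-statistic rankings (high
mean, high variance, low variance as a stable-expression negative control),
two highly-variable-gene recipes (dispersion z-scored within mean bins, and
a variance-stabilising-transform style standardised variance), a batch-aware
combination wrapper, and one supervised selector based on a Wilcoxon
rank-sum marker cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CellMatrix

__all__ = ["SelectorResult", "select", "select_batch_aware", "wilcoxon_markers",
           "SIMPLE_METHODS"]

SIMPLE_METHODS = (
    "all",
    "random",
    "high_mean",
    "high_variance",
    "low_variance",
    "hvg_binned_dispersion",
    "hvg_vst",
)


@dataclass
class SelectorResult:
    """An ordered feature set (most informative first) with per-feature scores."""

    method: str
    features: np.ndarray
    scores: np.ndarray
    n_requested: int | str
    batch_aware: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.features)) != self.features.size:
            raise ValueError("duplicate features in selection")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.features, "score": self.scores})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _cp10k_log1p(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * 1e4)


def _rank_order(scores: np.ndarray) -> np.ndarray:
    """Descending score order with stable index tie-break."""
    return np.argsort(-scores, kind="stable")


def select(
    ref: CellMatrix, method: str, n: int = 2000, seed: int = 0
) -> SelectorResult:
    """Select ``n`` features from the reference by a simple criterion.

    ``hvg_binned_dispersion`` ranks by log-dispersion of counts-per-10k
    z-scored within 20 bins of mean expression (see
    :func:`_binned_dispersion`). ``hvg_vst`` fits a degree-2 polynomial of
    log10 variance on log10 mean of the raw counts, standardises counts by
    the fitted standard deviation clipping at sqrt(n_cells), and ranks by
    the variance of the standardised values.
    """
    if method not in SIMPLE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {SIMPLE_METHODS}")
    counts = ref.dense_counts()
    n_features = ref.n_features
    if method != "all" and n > n_features:
        raise ValueError(f"n={n} exceeds {n_features} features")

    if method == "all":
        order = np.arange(n_features)
        scores = np.ones(n_features)
        n_requested: int | str = "auto"
    elif method == "random":
        rng = np.random.default_rng(seed)
        order = rng.choice(n_features, size=n, replace=False)
        scores = np.ones(n)
        n_requested = n
    else:
        if method == "high_mean":
            stat = counts.mean(axis=0)
        elif method == "high_variance":
            stat = counts.var(axis=0, ddof=1)
        elif method == "low_variance":
            # negative-control "stable expression" ranking; restrict to
            # expressed features so all-zero genes do not top the list
            var = counts.var(axis=0, ddof=1)
            expressed = counts.mean(axis=0) > 0
            stat = np.where(expressed, -var, -np.inf)
        elif method == "hvg_binned_dispersion":
            stat = _binned_dispersion(counts)
        else:  # hvg_vst
            stat = _vst_variance(counts)
        if not np.any(stat > np.nanmin(stat)):
            raise ValueError("degenerate input: statistic constant for all features")
        order = _rank_order(stat)[:n]
        scores = stat[order]
        n_requested = n
    if method in ("all", "random"):
        scores = scores[: order.size]
    return SelectorResult(
        method=method,
        features=ref.feature_ids[order],
        scores=np.asarray(scores, dtype=float),
        n_requested=n_requested,
        seed=seed,
    )


def _binned_dispersion(counts: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Log-dispersion of counts-per-10k, z-scored within 20 bins of mean.

    Dispersion (variance over mean) is computed on the normalised scale and
    log-transformed; genes are binned by log1p mean expression into
    equal-width bins and dispersions standardised within each bin, so a
    gene's score measures excess variability relative to genes of similar
    abundance.
    """
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    x = counts / totals * 1e4
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
        logdisp = np.where(disp > 0, np.log(disp), np.nan)
    bins = pd.cut(np.log1p(mean), bins=n_bins)
    df = pd.DataFrame({"disp": logdisp, "bin": bins})
    grouped = df.groupby("bin", observed=True)["disp"]
    mu = grouped.transform("mean").to_numpy()
    sd = grouped.transform("std").to_numpy()
    sd = np.where((sd == 0) | ~np.isfinite(sd), 1.0, sd)
    z = (logdisp - mu) / sd
    return np.where(np.isfinite(z), z, -np.inf)


def _vst_variance(counts: np.ndarray) -> np.ndarray:
    n_cells = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    usable = (mean > 0) & (var > 0)
    coef = np.polyfit(np.log10(mean[usable]), np.log10(var[usable]), deg=2)
    expected_sd = np.sqrt(10 ** np.polyval(coef, np.log10(np.where(usable, mean, 1.0))))
    expected_sd[~usable] = 1.0
    clip = np.sqrt(n_cells)
    z = np.clip((counts - mean[None, :]) / expected_sd[None, :], -clip, clip)
    out = z.var(axis=0, ddof=1)
    out[~usable] = 0.0
    return out


def select_batch_aware(
    ref: CellMatrix, method: str, n: int = 2000, seed: int = 0
) -> SelectorResult:
    """Batch-aware combination: select per batch, rank by how many batches
    choose each feature, break ties by median within-batch rank, truncate to n."""
    batches = np.unique(ref.batch)
    if batches.size < 2:
        raise ValueError("batch-aware selection needs >= 2 batches")
    per_batch: list[SelectorResult] = []
    for b in batches:
        sub = ref.subset_cells(ref.batch == b)
        if sub.n_cells < 2:
            warnings.warn(f"batch {b!r} has <2 cells; skipped")
            continue
        per_batch.append(select(sub, method, n=n, seed=seed))
    if not per_batch:
        raise ValueError("no usable batches")
    counts: dict = {}
    ranks: dict = {}
    for res in per_batch:
        for rank, feat in enumerate(res.features):
            counts[feat] = counts.get(feat, 0) + 1
            ranks.setdefault(feat, []).append(rank)
    feats = sorted(
        counts,
        key=lambda f: (-counts[f], float(np.median(ranks[f])), str(f)),
    )[:n]
    scores = np.array([counts[f] for f in feats], dtype=float)
    return SelectorResult(
        method=method,
        features=np.array(feats, dtype=object),
        scores=scores,
        n_requested=n,
        batch_aware=True,
        seed=seed,
    )


def wilcoxon_markers(
    ref: CellMatrix,
    n_per_label: int = 200,
    min_in: float = 0.10,
    max_out: float = 0.80,
    p_max: float = 0.1,
    combine: str = "union",
) -> SelectorResult:
    """Supervised marker selection via a Wilcoxon rank-sum cascade.

    Per label, each feature is tested label-vs-rest on log1p counts-per-10k.
    Features expressed (count > 0) in fewer than ``min_in`` of the label's
    cells, in more than ``max_out`` of the other cells, or with p-value above
    ``p_max`` are dropped; survivors are sorted by estimated log fold change
    and the top ``n_per_label`` kept. Per-label sets are combined by union or
    intersection.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    labels = np.unique(ref.label)
    if labels.size < 2:
        raise ValueError("need >= 2 labels for marker selection")
    counts = ref.dense_counts()
    x = _cp10k_log1p(counts)
    expressed = counts > 0

    per_label_sets: list[set] = []
    lfc_by_feature: dict = {}
    for lab in labels:
        in_mask = ref.label == lab
        if in_mask.sum() < 3:
            warnings.warn(f"label {lab!r} has <3 cells; skipped")
            continue
        frac_in = expressed[in_mask].mean(axis=0)
        frac_out = expressed[~in_mask].mean(axis=0)
        candidate = (frac_in >= min_in) & (frac_out <= max_out)
        if not candidate.any():
            per_label_sets.append(set())
            continue
        idx = np.flatnonzero(candidate)
        pvals = stats.ranksums(x[in_mask][:, idx], x[~in_mask][:, idx], axis=0).pvalue
        idx = idx[pvals <= p_max]
        if idx.size == 0:
            per_label_sets.append(set())
            continue
        eps = 1e-9
        lfc = np.log2(
            (np.expm1(x[in_mask][:, idx]).mean(axis=0) + eps)
            / (np.expm1(x[~in_mask][:, idx]).mean(axis=0) + eps)
        )
        top = _rank_order(lfc)[:n_per_label]
        keep, keep_lfc = idx[top], lfc[top]
        for f, v in zip(ref.feature_ids[keep], keep_lfc):
            lfc_by_feature[f] = max(lfc_by_feature.get(f, -np.inf), float(v))
        per_label_sets.append(set(ref.feature_ids[keep]))

    if not per_label_sets:
        raise ValueError("no usable labels")
    if combine == "union":
        final = set().union(*per_label_sets)
    else:
        final = set.intersection(*per_label_sets)
        if not final:
            warnings.warn("intersection of per-label marker sets is empty")
    feats = sorted(final, key=lambda f: (-lfc_by_feature.get(f, -np.inf), str(f)))
    return SelectorResult(
        method="wilcoxon",
        features=np.array(feats, dtype=object),
        scores=np.array([lfc_by_feature.get(f, np.nan) for f in feats]),
        n_requested="auto",
    )
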