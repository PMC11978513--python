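"""Baseline scaling, aggregation, ranking and metric profiling.

Raw metric scores are comparable neither across metrics (different
effective ranges) nor across datasets, so each (dataset, metric) pair is
rescaled linearly against the range spanned by four fixed baseline feature
sets. Scaled category means are combined into a single Overall score with
weights giving equal importance to building the reference (batch + bio) and
to using it (mapping + classification + unseen):

    Overall = 1/2 (IntBatch/2 + IntBio/2) + 1/2 (Mapping/3 + Class/3 + Unseen/3)

i.e. weights (1/4, 1/4, 1/6, 1/6, 1/6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CATEGORIES
from .metrics.config import SELECTED_METRICS

__all__ = [
    "BASELINE_METHODS",
    "CATEGORY_WEIGHTS",
    "CategorySummary",
    "scale_scores",
    "aggregate",
    "overall_score",
    "rank_methods",
    "standardize",
    "profile_metrics",
]

#: the four baseline feature sets anchoring the per-metric range: all
#: features; batch-aware HVG n=2,000; random n=500 averaged over 5 seeds;
#: a stable-expression negative control n=200
BASELINE_METHODS = ("baseline_all", "baseline_hvg_batch", "baseline_random",
                    "baseline_stable")

CATEGORY_WEIGHTS = {
    "batch": 0.25,
    "bio": 0.25,
    "mapping": 1.0 / 6.0,
    "classification": 1.0 / 6.0,
    "unseen": 1.0 / 6.0,
}


@dataclass
class CategorySummary:
    """Per-category mean scaled scores and the Overall score."""

    int_batch: float
    int_bio: float
    mapping: float
    classification: float
    unseen: float
    overall: float

    def as_dict(self) -> dict[str, float]:
        return {
            "batch": self.int_batch,
            "bio": self.int_bio,
            "mapping": self.mapping,
            "classification": self.classification,
            "unseen": self.unseen,
            "overall": self.overall,
        }


def overall_score(categories: dict[str, float]) -> float:
    """The weighted Overall score from the five category means."""
    return float(sum(CATEGORY_WEIGHTS[c] * categories[c] for c in CATEGORIES))


def scale_scores(
    raw: pd.DataFrame, baselines: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Scale raw scores by the min/max baseline score per (dataset, metric).

    ``baselines`` is a score table restricted to the baseline methods; if
    omitted, rows of ``raw`` whose method is in :data:`BASELINE_METHODS` are
    used. Scaled values outside [0, 1] are preserved, not clipped — a method
    may beat or trail every baseline. A degenerate baseline range yields a
    missing scaled value with a warning.
    """
    if baselines is None:
        baselines = raw[raw["method"].isin(BASELINE_METHODS)]
    if baselines.empty:
        raise ValueError("no baseline scores available")
    rng = (
        baselines.groupby(["dataset", "metric"])["value"]
        .agg(["min", "max", "count"])
        .rename(columns={"min": "lo", "max": "hi"})
    )
    if (rng["count"] < 2).any():
        bad = rng[rng["count"] < 2].index.tolist()
        raise ValueError(f"need >= 2 baseline values per (dataset, metric): {bad}")
    out = raw.merge(rng.reset_index(), on=["dataset", "metric"], how="left")
    if out["lo"].isna().any():
        missing = out[out["lo"].isna()][["dataset", "metric"]].drop_duplicates()
        raise ValueError(
            f"baselines missing for: {missing.to_records(index=False).tolist()}"
        )
    span = out["hi"] - out["lo"]
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} scores undefined: baseline range is zero"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["scaled"] = np.where(
            degenerate, np.nan, (out["value"] - out["lo"]) / span
        )
    return out.drop(columns=["lo", "hi", "count"])


def aggregate(
    scaled: pd.DataFrame, category_map: dict[str, str] | None = None
) -> CategorySummary:
    """Category means and the Overall score for one (dataset, method) table.

    ``category_map`` assigns metrics to categories; the default is the final
    selected set (optional metrics excluded). Metrics absent from the map
    are ignored; missing scaled values are excluded from their category mean.
    """
    category_map = category_map or SELECTED_METRICS
    sub = scaled[scaled["metric"].isin(category_map)]
    cats: dict[str, float] = {}
    for c in CATEGORIES:
        names = [m for m, cat in category_map.items() if cat == c]
        vals = sub[sub["metric"].isin(names)]["scaled"].dropna()
        if vals.empty:
            raise ValueError(f"category {c!r} has no scores; overall undefined")
        cats[c] = float(vals.mean())
    return CategorySummary(
        int_batch=cats["batch"],
        int_bio=cats["bio"],
        mapping=cats["mapping"],
        classification=cats["classification"],
        unseen=cats["unseen"],
        overall=overall_score(cats),
    )


def rank_methods(summaries: pd.DataFrame, score_col: str = "overall") -> pd.DataFrame:
    """Rank methods within each dataset and average ranks across datasets.

    ``summaries`` needs columns dataset, method and ``score_col``. Ranks are
    descending (best = 1) with ties averaged; the cross-dataset rank is the
    mean of per-dataset ranks with its standard deviation. Missing
    method-dataset cells are excluded from that dataset's ranking and
    flagged in ``n_datasets``.
    """
    if summaries["method"].nunique() < 2:
        raise ValueError("ranking needs >= 2 methods")
    df = summaries.dropna(subset=[score_col]).copy()
    df["rank"] = df.groupby("dataset")[score_col].rank(
        ascending=False, method="average"
    )
    out = (
        df.groupby("method")["rank"]
        .agg(mean_rank="mean", sd_rank="std", n_datasets="count")
        .reset_index()
        .sort_values("mean_rank", kind="stable")
        .reset_index(drop=True)
    )
    return out


def standardize(scores: pd.DataFrame, group_cols, value_col: str = "scaled"
                ) -> pd.Series:
    """Z-score values within groups (sample s.d.; constant groups map to 0)."""
    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.zeros(x.size), index=x.index)
        return (x - x.mean()) / sd

    return scores.groupby(list(group_cols))[value_col].transform(_z)


def profile_metrics(
    scores: pd.DataFrame,
    technical_factors: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Profile metric behavior over random and ordered feature subsets.

    ``scores`` needs columns metric, value, n_features and set_type
    ("random" for unordered sets used for observed ranges, "ordered" for
    ranked sets used for the feature-count correlation), plus optionally
    dataset. Returns the observed range per metric, the Pearson correlation
    with the number of features, correlations with any supplied per-row
    technical factors, and the full inter-metric correlation matrix. A
    metric with zero observed range cannot distinguish feature sets and is a
    candidate for exclusion.
    """
    required = {"metric", "value", "n_features", "set_type"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    df = scores.copy()
    if "dataset" not in df.columns:
        df["dataset"] = "dataset"

    rnd = df[df["set_type"] == "random"]
    ranges = (
        rnd.groupby(["metric", "dataset"])["value"]
        .agg(lambda v: v.max() - v.min())
        .groupby("metric")
        .mean()
        .rename("observed_range")
        .reset_index()
    )

    def _safe_corr(x, y):
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    ordered = df[df["set_type"] == "ordered"]
    if ordered.empty:
        nf_corr = pd.DataFrame(columns=["metric", "corr_n_features"])
    else:
        nf_corr = (
            ordered.groupby("metric")
            .apply(
                lambda g: _safe_corr(g["n_features"].to_numpy(float),
                                     g["value"].to_numpy(float)),
                include_groups=False,
            )
            .rename("corr_n_features")
            .reset_index()
        )
    profile = ranges.merge(nf_corr, on="metric", how="outer")
    if profile[["observed_range", "corr_n_features"]].isna().any().any():
        warnings.warn("some metric profiles are undefined (constant scores)")

    out = {"profile": profile}
    if technical_factors is not None:
        rows = []
        joined = rnd.join(technical_factors, how="inner") \
            if technical_factors.index.equals(rnd.index) \
            else rnd.merge(technical_factors, on="dataset", how="left")
        for metric, g in joined.groupby("metric"):
            for factor in technical_factors.columns.drop("dataset", errors="ignore"):
                rows.append(
                    {
                        "metric": metric,
                        "factor": factor,
                        "correlation": _safe_corr(
                            g["value"].to_numpy(float),
                            g[factor].to_numpy(float),
                        ),
                    }
                )
        out["technical"] = pd.DataFrame(rows)

    wide = df.pivot_table(
        index=["dataset", "set_type", "n_features"],
        columns="metric",
        values="value",
        aggfunc="mean",
    )
    out["inter_metric"] = wide.corr(method="pearson")
    return out
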