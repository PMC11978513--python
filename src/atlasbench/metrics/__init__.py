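"""Benchmark metrics in five categories.

Integration (Batch): batch PCR, CMS, iLISI. Integration (Bio): isolated
label ASW/F1, bNMI, cLISI, ldfDiff, graph connectivity. Mapping: cell
distance, label distance, mLISI, qLISI (plus optional kNN correlation).
Classification: accuracy/F1/Jaccard/MCC/AUPRC families (F1 micro/macro/
rarity are the selected three). Unseen populations: Milo-style neighborhood
enrichment, unseen cell distance, unseen label distance (plus optional
uncertainty). Every metric returns a raw score in [0, 1], higher is better.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core_data import JointEmbedding, SplitDataset
from ..transfer import TransferResult
from .config import MetricConfig, MetricScore, OPTIONAL_METRICS, SELECTED_METRICS
from .batch import batch_pcr, cms_score, lisi_score, pcr, per_cell_lisi
from .bio import (
    balanced_nmi,
    bnmi,
    cluster_sweep,
    graph_connectivity,
    isolated_label_scores,
    ldf_diff,
    leiden_sweep,
)
from .classification import classification_scores, rarity_weighted
from .mapping import cell_distance, knn_correlation, label_distance
from .unseen import (
    milo_score,
    unseen_cell_distance,
    unseen_label_distance,
    unseen_uncertainty,
)

__all__ = [
    "MetricConfig",
    "MetricScore",
    "SELECTED_METRICS",
    "OPTIONAL_METRICS",
    "lisi_score",
    "per_cell_lisi",
    "batch_pcr",
    "pcr",
    "cms_score",
    "leiden_sweep",
    "cluster_sweep",
    "balanced_nmi",
    "bnmi",
    "isolated_label_scores",
    "graph_connectivity",
    "ldf_diff",
    "cell_distance",
    "label_distance",
    "knn_correlation",
    "classification_scores",
    "rarity_weighted",
    "unseen_uncertainty",
    "unseen_cell_distance",
    "unseen_label_distance",
    "milo_score",
    "compute_all",
    "scores_to_table",
]


def compute_all(
    ds: SplitDataset,
    emb: JointEmbedding,
    tr: TransferResult,
    cfg: MetricConfig | None = None,
    include_optional: bool = False,
) -> list[MetricScore]:
    """Compute the full selected metric set for one integrated embedding.

    Returns one :class:`MetricScore` per metric in the final selected set
    (and the optional extras when requested). Mapping and unseen distance
    metrics use ground-truth query labels; transferred labels are scored by
    the classification metrics.
    """
    cfg = cfg or MetricConfig()
    ref, query = ds.reference, ds.query
    unseen = ds.unseen_labels
    origin = np.r_[
        np.zeros(ref.n_cells, dtype=int), np.ones(query.n_cells, dtype=int)
    ]
    all_batch = np.concatenate([ref.batch, query.batch])
    all_labels = np.concatenate([ref.label, query.label])
    is_query = origin.astype(bool)

    scores: list[MetricScore] = []
    # Integration (Batch)
    scores.append(batch_pcr(emb, ref.batch, cfg=cfg))
    scores.append(cms_score(emb.ref_coords, ref.batch, cfg))
    scores.append(lisi_score(emb.ref_coords, ref.batch, "ilisi", cfg))
    # Integration (Bio)
    clusterings = leiden_sweep(emb.ref_coords, cfg)
    scores.append(bnmi(emb.ref_coords, ref.label, ref.batch, cfg, clusterings))
    asw, f1 = isolated_label_scores(
        emb.ref_coords, ref.label, ref.batch, cfg, clusterings
    )
    scores.extend([asw, f1])
    scores.append(lisi_score(emb.ref_coords, ref.label, "clisi", cfg))
    scores.append(graph_connectivity(emb.ref_coords, ref.label, cfg))
    if emb.pre_integration is not None:
        scores.append(ldf_diff(emb, all_batch, cfg))
    # Mapping
    scores.append(cell_distance(emb, ref.label, query.label, unseen, cfg))
    scores.append(label_distance(emb, ref.label, query.label, unseen, cfg))
    scores.append(lisi_score(emb.all_coords, origin, "mlisi", cfg))
    if np.unique(query.batch).size >= 2:
        scores.append(lisi_score(emb.query_coords, query.batch, "qlisi", cfg))
    # Classification
    cls = classification_scores(tr, query.label, unseen)
    scores.extend(cls[name] for name in ("f1_micro", "f1_macro", "f1_rarity"))
    # Unseen
    if unseen:
        scores.append(
            milo_score(emb, all_batch, is_query, all_labels, unseen, cfg)
        )
        scores.append(
            unseen_cell_distance(emb, ref.label, query.label, unseen, cfg)
        )
        scores.append(
            unseen_label_distance(emb, ref.label, query.label, unseen, cfg)
        )
    if include_optional:
        scores.append(knn_correlation(ds, emb, cfg=cfg))
        if unseen:
            mask = np.isin(query.label, list(unseen))
            scores.append(unseen_uncertainty(tr, mask))
    return scores


def scores_to_table(
    scores: list[MetricScore], dataset: str, method: str
) -> pd.DataFrame:
    """Arrange metric scores as a tidy score table."""
    return pd.DataFrame(
        {
            "dataset": dataset,
            "method": method,
            "metric": [s.name for s in scores],
            "category": [s.category for s in scores],
            "value": [s.value for s in scores],
        }
    )
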