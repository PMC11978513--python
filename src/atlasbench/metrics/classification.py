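"""Label-transfer classification metrics.

Standard confusion-matrix scores of the transferred query labels against the
ground truth, with micro, macro and rarity-weighted averages. Rarity weights
are proportional to the inverse true class size, emphasising rare
populations. Query cells of unseen labels are excluded — no correct
reference class exists for them.
"""

from __future__ import annotations

import numpy as np

from ..transfer import TransferResult
from .config import MetricScore

__all__ = ["classification_scores", "rarity_weighted"]


def rarity_weighted(per_class: np.ndarray, class_counts: np.ndarray) -> float:
    """Average per-class scores with weights proportional to 1/n_class."""
    w = 1.0 / np.asarray(class_counts, dtype=float)
    return float((per_class * w).sum() / w.sum())


def classification_scores(
    tr: TransferResult, true_labels, unseen_labels=()
) -> dict[str, MetricScore]:
    """All classification metrics for one transfer result.

    Returns accuracy, F1 and Jaccard (micro/macro/rarity averages), Matthews
    correlation rescaled to [0, 1], and macro-averaged area under the
    precision-recall curve from the probability columns. Reference classes
    absent from the query truth are skipped for macro and rarity averages.
    """
    from sklearn import metrics as skm

    true_labels = np.asarray(true_labels, dtype=object)
    keep = ~np.isin(true_labels, list(unseen_labels))
    y_true = true_labels[keep].astype(str)
    y_pred = tr.predicted[keep].astype(str)
    proba = tr.probabilities[keep]
    classes = tr.classes.astype(str)
    present = [c for c in classes if (y_true == c).sum() > 0]
    counts = np.array([(y_true == c).sum() for c in present])
    skipped = [c for c in classes if c not in present]
    notes = f"classes skipped (absent from query): {skipped}" if skipped else ""

    n = y_true.size
    out: dict[str, MetricScore] = {}

    def add(name, value):
        out[name] = MetricScore(name, "classification", float(value),
                                n_cells_used=n, notes=notes)

    add("accuracy", skm.accuracy_score(y_true, y_pred))
    f1_per = skm.f1_score(y_true, y_pred, labels=present, average=None,
                          zero_division=0)
    jac_per = skm.jaccard_score(y_true, y_pred, labels=present, average=None,
                                zero_division=0)
    add("f1_micro", skm.f1_score(y_true, y_pred, labels=present,
                                 average="micro", zero_division=0))
    add("f1_macro", float(np.mean(f1_per)))
    add("f1_rarity", rarity_weighted(f1_per, counts))
    add("jaccard_micro", skm.jaccard_score(y_true, y_pred, labels=present,
                                           average="micro", zero_division=0))
    add("jaccard_macro", float(np.mean(jac_per)))
    add("jaccard_rarity", rarity_weighted(jac_per, counts))
    add("mcc01", (skm.matthews_corrcoef(y_true, y_pred) + 1.0) / 2.0)
    ap = [
        skm.average_precision_score(
            (y_true == c).astype(int), proba[:, list(classes).index(c)]
        )
        for c in present
    ]
    add("auprc_macro", float(np.mean(ap)))
    return out
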