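"""Label transfer from an integrated reference to mapped query cells.

A multinomial logistic regression classifier is trained on the reference
cells' embedding coordinates and ground-truth labels; query cells receive
the full probability vector over reference labels and the argmax label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import JointEmbedding

__all__ = ["TransferResult", "transfer_labels"]


@dataclass
class TransferResult:
    """Per-query-cell predicted label plus the full probability vector."""

    predicted: np.ndarray
    probabilities: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=object)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.probabilities.shape != (self.predicted.size, self.classes.size):
            raise ValueError("probability matrix shape mismatch")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.probabilities, columns=[f"p_{c}" for c in self.classes]
        )
        df.insert(0, "predicted", self.predicted)
        if cell_ids is not None:
            df.insert(0, "cell_id", np.asarray(cell_ids))
        return df

    def write_tsv(self, path, cell_ids=None) -> None:
        self.to_frame(cell_ids).to_csv(path, sep="\t", index=False)


def transfer_labels(
    emb: JointEmbedding,
    ref_labels,
    regularization: float = 1.0,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> TransferResult:
    """Fit the reference classifier and predict query labels.

    ``regularization`` is the inverse L2 penalty strength (sklearn's ``C``).
    Classes are ordered lexicographically; argmax ties resolve to the first
    class in that order.
    """
    from sklearn.linear_model import LogisticRegression

    ref_labels = np.asarray(ref_labels, dtype=object)
    if ref_labels.size != emb.ref_coords.shape[0]:
        raise ValueError("ref_labels must align with reference coordinates")
    if np.unique(ref_labels).size < 2:
        raise ValueError("need >= 2 reference labels")

    clf = LogisticRegression(
        C=regularization,
        solver="lbfgs",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    clf.fit(emb.ref_coords, ref_labels.astype(str))
    proba = clf.predict_proba(emb.query_coords)
    proba = proba / proba.sum(axis=1, keepdims=True)
    classes = np.asarray(clf.classes_, dtype=object)  # lexicographic via np.unique
    predicted = classes[np.argmax(proba, axis=1)]  # ties -> first class in order
    return TransferResult(predicted=predicted, probabilities=proba, classes=classes)
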