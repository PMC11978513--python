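"""Shared configuration and the score container for all metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core_data import CATEGORIES

__all__ = ["MetricConfig", "MetricScore", "SELECTED_METRICS", "OPTIONAL_METRICS"]

#: the benchmark's final metric set with its category assignment
#: (graph connectivity sits with the biology-conservation metrics)
SELECTED_METRICS = {
    "batch_pcr": "batch",
    "cms": "batch",
    "ilisi": "batch",
    "isolated_label_asw": "bio",
    "isolated_label_f1": "bio",
    "bnmi": "bio",
    "clisi": "bio",
    "ldf_diff": "bio",
    "graph_connectivity": "bio",
    "cell_distance": "mapping",
    "label_distance": "mapping",
    "mlisi": "mapping",
    "qlisi": "mapping",
    "f1_macro": "classification",
    "f1_micro": "classification",
    "f1_rarity": "classification",
    "milo": "unseen",
    "unseen_cell_distance": "unseen",
    "unseen_label_distance": "unseen",
}

#: defined but excluded from default category means
OPTIONAL_METRICS = {
    "knn_correlation": "mapping",
    "unseen_uncertainty": "unseen",
}


@dataclass
class MetricConfig:
    """Tunable parameters shared across metrics.

    ``milo_k`` and ``milo_subset`` encode the neighborhood-size rule
    (five times the number of batches, capped at 200) and the index-cell
    subsample rule (20,000 cells or 10% of the dataset, whichever is
    higher).
    """

    lisi_perplexity: float = 30.0
    knn_k_graph: int = 90
    cms_k: int = 75
    cms_alpha: float = 0.1
    cell_dist_quantile: float = 0.90
    label_min_query_cells: int = 20
    knn_corr_k: int = 100
    milo_fdr: float = 0.1
    milo_k_cap: int = 200
    milo_k_per_batch: int = 5
    milo_subset_min: int = 20_000
    milo_subset_frac: float = 0.10
    leiden_resolutions: tuple[float, ...] = tuple(
        round(0.1 * i, 1) for i in range(1, 21)
    )
    cov_shrinkage_eps: float = 1e-6
    ldf_bound: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cms_alpha < 1 or not 0 < self.milo_fdr < 1:
            raise ValueError("alpha/FDR levels must be in (0, 1)")
        if not 0 < self.cell_dist_quantile < 1:
            raise ValueError("cell_dist_quantile must be in (0, 1)")
        for name in ("lisi_perplexity", "knn_k_graph", "cms_k", "knn_corr_k",
                     "ldf_bound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def milo_k(self, n_batches: int) -> int:
        return min(self.milo_k_per_batch * n_batches, self.milo_k_cap)

    def milo_subset(self, n_cells: int) -> int:
        return int(max(self.milo_subset_min, self.milo_subset_frac * n_cells))


@dataclass
class MetricScore:
    """A named raw score in [0, 1]; higher is always better."""

    name: str
    category: str
    value: float
    n_cells_used: int = 0
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if np.isfinite(self.value) and not -1e-9 <= self.value <= 1 + 1e-9:
            raise ValueError(f"{self.name}: value {self.value} outside [0, 1]")
        self.value = float(np.clip(self.value, 0.0, 1.0))
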