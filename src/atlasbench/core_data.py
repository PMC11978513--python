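"""Data containers and I/O for the benchmark.

The benchmark operates on a reference/query split of an annotated count
matrix: the reference is the multi-batch dataset an atlas embedding is built
from, the query the held-out batches mapped into that embedding afterwards.
``prepare_split`` applies the standard preprocessing: cell quality filters,
the split by batch, removal of small labels, removal of the designated
"unseen" populations from the reference, and removal of features not
expressed in the reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CellMatrix",
    "SplitDataset",
    "JointEmbedding",
    "ConfigurationError",
    "read_dataset",
    "prepare_split",
    "write_scores",
    "read_scores",
    "write_split_h5ad",
    "read_split_h5ad",
    "read_embedding_h5ad",
    "write_embedding_h5ad",
    "CATEGORIES",
]

CATEGORIES = ("batch", "bio", "mapping", "classification", "unseen")

#: cells above this size are kept sparse internally; below, densified
DENSE_CELL_LIMIT = 50_000


class ConfigurationError(ValueError):
    """Raised when inputs reference keys, files or labels that do not exist."""


def _as_counts(x) -> np.ndarray | sparse.csr_matrix:
    """Canonicalise a counts matrix: dense float64 below the size limit."""
    if sparse.issparse(x):
        x = sparse.csr_matrix(x)
        if x.shape[0] <= DENSE_CELL_LIMIT:
            return np.asarray(x.todense(), dtype=np.float64)
        return x.astype(np.float64)
    return np.asarray(x, dtype=np.float64)


@dataclass
class CellMatrix:
    """A cells x features count matrix with per-cell batch and label annotations.

    Cells are rows everywhere; every per-cell vector is row-aligned with
    ``counts``.
    """

    counts: np.ndarray | sparse.csr_matrix
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    batch: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.counts = _as_counts(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        n, p = self.counts.shape
        if self.cell_ids.shape != (n,):
            raise ValueError(f"cell_ids length {self.cell_ids.size} != {n} cells")
        if self.feature_ids.shape != (p,):
            raise ValueError(
                f"feature_ids length {self.feature_ids.size} != {p} features"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")
        for name, vec in (("batch", self.batch), ("label", self.label)):
            if vec.shape != (n,):
                raise ValueError(f"{name} length {vec.size} != {n} cells")
        data = self.counts.data if sparse.issparse(self.counts) else self.counts
        if not np.all(np.isfinite(data)):
            raise ValueError("counts contain non-finite values")
        if data.size and data.min() < 0:
            raise ValueError("counts contain negative values")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def dense_counts(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return self.counts

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        return CellMatrix(
            counts=self.counts[mask],
            cell_ids=self.cell_ids[mask],
            feature_ids=self.feature_ids,
            batch=self.batch[mask],
            label=self.label[mask],
        )

    def subset_features(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        return CellMatrix(
            counts=self.counts[:, mask],
            cell_ids=self.cell_ids,
            feature_ids=self.feature_ids[mask],
            batch=self.batch,
            label=self.label,
        )


@dataclass
class SplitDataset:
    """Reference and query halves with the designated unseen-label set."""

    reference: CellMatrix
    query: CellMatrix
    unseen_labels: frozenset
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unseen_labels = frozenset(self.unseen_labels)
        if not np.array_equal(self.reference.feature_ids, self.query.feature_ids):
            raise ValueError("reference and query feature ids differ")
        bad = self.unseen_labels & set(self.reference.label)
        if bad:
            raise ValueError(f"unseen labels present in reference: {sorted(bad)}")

    @property
    def n_features(self) -> int:
        return self.reference.n_features


@dataclass
class JointEmbedding:
    """Reference and mapped-query coordinates in one shared latent space.

    ``pre_integration`` optionally holds coordinates of all cells (reference
    rows first, then query rows) in a common unintegrated space, used by
    comparison metrics such as batch PCR and ldfDiff.
    """

    ref_coords: np.ndarray
    query_coords: np.ndarray
    pre_integration: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ref_coords = np.asarray(self.ref_coords, dtype=np.float64)
        self.query_coords = np.asarray(self.query_coords, dtype=np.float64)
        if self.ref_coords.ndim != 2 or self.query_coords.ndim != 2:
            raise ValueError("coordinates must be 2-D matrices")
        if self.ref_coords.shape[1] != self.query_coords.shape[1]:
            raise ValueError("reference and query dimensions differ")
        for arr in (self.ref_coords, self.query_coords):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite coordinates")
        if self.pre_integration is not None:
            self.pre_integration = np.asarray(self.pre_integration, dtype=np.float64)
            n = self.ref_coords.shape[0] + self.query_coords.shape[0]
            if self.pre_integration.shape[0] != n:
                raise ValueError(
                    "pre_integration rows must cover reference then query cells"
                )

    @property
    def d(self) -> int:
        return self.ref_coords.shape[1]

    @property
    def all_coords(self) -> np.ndarray:
        return np.vstack([self.ref_coords, self.query_coords])


# ---------------------------------------------------------------------------
# H5AD I/O


def read_dataset(
    path,
    batch_key: str,
    label_key: str,
    query_batches,
    unseen_labels=(),
    layer: str | None = None,
    round_counts: bool = False,
) -> tuple[CellMatrix, np.ndarray]:
    """Read an H5AD file into a :class:`CellMatrix` plus a query-cell mask.

    Counts are taken from ``X`` or the named ``layer``; batch and label come
    from ``obs``. Non-integer counts raise unless ``round_counts`` is set.
    """
    import anndata as ad

    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"file not found: {path}")
    adata = ad.read_h5ad(path)
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix")
    for key in (batch_key, label_key):
        if key not in adata.obs.columns:
            raise ConfigurationError(
                f"obs key {key!r} not found; available columns: "
                f"{sorted(adata.obs.columns)}"
            )
    x = adata.layers[layer] if layer is not None else adata.X
    if layer is not None and layer not in adata.layers:
        raise ConfigurationError(f"layer {layer!r} not found")
    counts = _as_counts(x)
    data = counts.data if sparse.issparse(counts) else counts
    if not np.allclose(data, np.round(data)):
        if round_counts:
            import warnings

            warnings.warn("non-integer counts rounded", stacklevel=2)
            if sparse.issparse(counts):
                counts.data = np.round(counts.data)
            else:
                counts = np.round(counts)
        else:
            raise ValueError("counts are not integers (set round_counts to round)")
    batch = adata.obs[batch_key].astype(str).to_numpy()
    query_batches = set(map(str, query_batches))
    missing = query_batches - set(batch)
    if missing:
        raise ConfigurationError(f"query batches not present: {sorted(missing)}")
    cm = CellMatrix(
        counts=counts,
        cell_ids=adata.obs_names.to_numpy(),
        feature_ids=adata.var_names.to_numpy(),
        batch=batch,
        label=adata.obs[label_key].astype(str).to_numpy(),
    )
    is_query = np.isin(cm.batch, list(query_batches))
    return cm, is_query


def write_split_h5ad(ds: SplitDataset, path) -> None:
    """Write a split dataset to H5AD with annotations in standard locations."""
    import anndata as ad

    n_ref = ds.reference.n_cells
    counts = (
        sparse.vstack(
            [sparse.csr_matrix(ds.reference.counts), sparse.csr_matrix(ds.query.counts)]
        )
        if sparse.issparse(ds.reference.counts) or sparse.issparse(ds.query.counts)
        else np.vstack([ds.reference.dense_counts(), ds.query.dense_counts()])
    )
    obs = pd.DataFrame(
        {
            "batch": np.concatenate([ds.reference.batch, ds.query.batch]),
            "label": np.concatenate([ds.reference.label, ds.query.label]),
            "is_query": np.r_[np.zeros(n_ref, bool), np.ones(ds.query.n_cells, bool)],
        },
        index=np.concatenate([ds.reference.cell_ids, ds.query.cell_ids]).astype(str),
    )
    adata = ad.AnnData(X=counts, obs=obs)
    adata.var_names = ds.reference.feature_ids.astype(str)
    adata.uns["unseen_labels"] = sorted(ds.unseen_labels)
    adata.uns["provenance"] = json.dumps(ds.provenance)
    adata.write_h5ad(Path(path))


def read_embedding_h5ad(
    path, emb_key: str = "X_emb", pre_key: str | None = "X_pre"
) -> JointEmbedding:
    """Read a joint embedding stored in a split H5AD's ``obsm`` slots.

    ``emb_key`` holds the integrated coordinates for all cells (reference
    rows first, query rows after, as written by :func:`write_split_h5ad`);
    ``pre_key`` optionally holds a common pre-integration embedding.
    """
    import anndata as ad

    adata = ad.read_h5ad(Path(path))
    if emb_key not in adata.obsm:
        raise ConfigurationError(
            f"obsm key {emb_key!r} not found; available: {sorted(adata.obsm)}"
        )
    coords = np.asarray(adata.obsm[emb_key], dtype=np.float64)
    is_query = adata.obs["is_query"].to_numpy(bool)
    pre = None
    if pre_key is not None and pre_key in adata.obsm:
        pre = np.asarray(adata.obsm[pre_key], dtype=np.float64)
    return JointEmbedding(
        ref_coords=coords[~is_query],
        query_coords=coords[is_query],
        pre_integration=pre,
    )


def write_embedding_h5ad(path, emb: JointEmbedding, emb_key: str = "X_emb",
                         pre_key: str = "X_pre") -> None:
    """Attach a joint embedding to an existing split H5AD's ``obsm``."""
    import anndata as ad

    adata = ad.read_h5ad(Path(path))
    n = emb.ref_coords.shape[0] + emb.query_coords.shape[0]
    if adata.n_obs != n:
        raise ValueError("embedding rows do not match the dataset's cells")
    adata.obsm[emb_key] = emb.all_coords
    if emb.pre_integration is not None:
        adata.obsm[pre_key] = emb.pre_integration
    adata.write_h5ad(Path(path))


def read_split_h5ad(path) -> SplitDataset:
    """Read a split dataset written by :func:`write_split_h5ad`."""
    import anndata as ad

    adata = ad.read_h5ad(Path(path))
    is_query = adata.obs["is_query"].to_numpy(bool)

    def _half(mask):
        sub = adata[mask]
        return CellMatrix(
            counts=_as_counts(sub.X),
            cell_ids=sub.obs_names.to_numpy(),
            feature_ids=sub.var_names.to_numpy(),
            batch=sub.obs["batch"].astype(str).to_numpy(),
            label=sub.obs["label"].astype(str).to_numpy(),
        )

    provenance = json.loads(adata.uns.get("provenance", "{}"))
    return SplitDataset(
        reference=_half(~is_query),
        query=_half(is_query),
        unseen_labels=frozenset(adata.uns.get("unseen_labels", [])),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Preprocessing / split


def prepare_split(
    raw: CellMatrix,
    query_batches,
    unseen_labels=(),
    min_counts: int = 100,
    min_features: int = 100,
    min_label_cells: int = 20,
) -> SplitDataset:
    """Apply the preprocessing filters and split into reference and query.

    Stage order: cell quality control (total counts, detected features) ->
    split by batch -> per-half small-label removal -> unseen-label removal
    from the reference -> removal of features not expressed in the reference.
    The provenance dict records the number of cells/features removed at every
    stage, so counts in always equal counts out plus counts removed.
    """
    import warnings

    query_batches = set(map(str, query_batches))
    unseen_labels = set(map(str, unseen_labels))
    if not query_batches:
        raise ConfigurationError("query_batches must be nonempty")
    missing = query_batches - set(raw.batch)
    if missing:
        raise ConfigurationError(f"query batches not present: {sorted(missing)}")

    prov: dict = {"cells_in": raw.n_cells, "features_in": raw.n_features}

    # cell QC
    counts = raw.counts
    if sparse.issparse(counts):
        totals = np.asarray(counts.sum(axis=1)).ravel()
        detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    else:
        totals = counts.sum(axis=1)
        detected = (counts > 0).sum(axis=1)
    keep = (totals >= min_counts) & (detected >= min_features)
    prov["cells_removed_qc"] = int((~keep).sum())
    qc = raw.subset_cells(keep)

    batches_before = set(raw.batch)
    lost = batches_before - set(qc.batch)
    if lost:
        warnings.warn(f"all cells of batch(es) removed by QC: {sorted(lost)}")

    # split
    is_query = np.isin(qc.batch, list(query_batches))
    ref = qc.subset_cells(~is_query)
    query = qc.subset_cells(is_query)
    prov["cells_reference_after_split"] = ref.n_cells
    prov["cells_query_after_split"] = query.n_cells

    # small-label filter, applied per half
    def _drop_small(cm: CellMatrix, stage: str) -> CellMatrix:
        sizes = pd.Series(cm.label).value_counts()
        small = set(sizes[sizes < min_label_cells].index)
        keep = ~np.isin(cm.label, list(small))
        prov[stage] = int((~keep).sum())
        prov[stage + "_labels"] = sorted(small)
        return cm.subset_cells(keep)

    ref = _drop_small(ref, "cells_removed_small_labels_reference")
    query = _drop_small(query, "cells_removed_small_labels_query")

    # unseen labels removed from the reference only
    missing_unseen = unseen_labels - set(query.label)
    if missing_unseen:
        raise ConfigurationError(
            f"unseen labels absent from query: {sorted(missing_unseen)}"
        )
    keep = ~np.isin(ref.label, list(unseen_labels))
    prov["cells_removed_unseen_reference"] = int((~keep).sum())
    ref = ref.subset_cells(keep)

    # features not expressed in the reference dropped from both halves
    rc = ref.counts
    expressed = (
        np.asarray((rc > 0).sum(axis=0)).ravel() > 0
        if sparse.issparse(rc)
        else (rc > 0).sum(axis=0) > 0
    )
    prov["features_removed_unexpressed"] = int((~expressed).sum())
    ref = ref.subset_features(expressed)
    query = query.subset_features(expressed)

    prov["cells_out_reference"] = ref.n_cells
    prov["cells_out_query"] = query.n_cells
    prov["features_out"] = ref.n_features
    return SplitDataset(
        reference=ref,
        query=query,
        unseen_labels=frozenset(unseen_labels),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Score tables

_SCORE_COLUMNS = ["dataset", "method", "metric", "category", "value"]


def _validate_scores(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    bad = set(table["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    return table[_SCORE_COLUMNS]


def write_scores(table: pd.DataFrame, path) -> None:
    """Write a score table as TSV; NaN values are preserved as empty fields."""
    _validate_scores(table).to_csv(Path(path), sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    """Read a score table; warns if missing values are present."""
    import warnings

    table = pd.read_csv(Path(path), sep="\t")
    table = _validate_scores(table)
    table["value"] = pd.to_numeric(table["value"])
    if table["value"].isna().any():
        warnings.warn(f"{int(table['value'].isna().sum())} missing score values")
    return table
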