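import numpy as np
import pandas as pd
import pytest

import atlasbench as ab
from atlasbench.core_data import ConfigurationError, prepare_split


def _raw(counts, batch, label, cell_prefix="c"):
    counts = np.asarray(counts, float)
    return ab.CellMatrix(
        counts=counts,
        cell_ids=np.array([f"{cell_prefix}{i}" for i in range(counts.shape[0])]),
        feature_ids=np.array([f"g{j}" for j in range(counts.shape[1])]),
        batch=np.array(batch, object),
        label=np.array(label, object),
    )


class TestCellMatrix:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate cell"):
            ab.CellMatrix(
                counts=np.ones((2, 2)),
                cell_ids=["c", "c"],
                feature_ids=["f1", "f2"],
                batch=["a", "a"],
                label=["x", "x"],
            )

    def test_rejects_negative_and_nonfinite(self):
        for bad in (-1.0, np.nan):
            with pytest.raises(ValueError):
                ab.CellMatrix(
                    counts=np.array([[1.0, bad]]),
                    cell_ids=["c"],
                    feature_ids=["f1", "f2"],
                    batch=["a"],
                    label=["x"],
                )

    def test_annotation_length_checked(self):
        with pytest.raises(ValueError, match="batch"):
            ab.CellMatrix(
                counts=np.ones((2, 2)),
                cell_ids=["c1", "c2"],
                feature_ids=["f1", "f2"],
                batch=["a"],
                label=["x", "x"],
            )


class TestReadDataset:
    def _h5ad(self, tmp_path, obs=None, n=4, p=3):
        import anndata as ad

        rng = np.random.default_rng(0)
        obs = obs if obs is not None else pd.DataFrame(
            {
                "tech": ["t1", "t1", "t2", "t2"][:n],
                "celltype": ["x", "y", "x", "y"][:n],
            },
            index=[f"c{i}" for i in range(n)],
        )
        adata = ad.AnnData(
            X=rng.integers(0, 10, (n, p)).astype(float), obs=obs
        )
        path = tmp_path / "toy.h5ad"
        adata.write_h5ad(path)
        return path

    def test_field_mapping(self, tmp_path):
        path = self._h5ad(tmp_path)
        cm, is_query = ab.read_dataset(
            path, batch_key="tech", label_key="celltype", query_batches={"t2"}
        )
        assert list(cm.batch) == ["t1", "t1", "t2", "t2"]
        assert list(cm.label) == ["x", "y", "x", "y"]
        assert list(is_query) == [False, False, True, True]

    def test_missing_key_lists_columns(self, tmp_path):
        path = self._h5ad(tmp_path)
        with pytest.raises(ConfigurationError, match="celltype"):
            ab.read_dataset(
                path, batch_key="tech", label_key="missing", query_batches={"t2"}
            )

    def test_empty_matrix_errors(self, tmp_path):
        import anndata as ad

        path = tmp_path / "empty.h5ad"
        ad.AnnData(
            X=np.zeros((0, 3)), obs=pd.DataFrame({"tech": [], "celltype": []})
        ).write_h5ad(path)
        with pytest.raises(ValueError, match="empty"):
            ab.read_dataset(
                path, batch_key="tech", label_key="celltype", query_batches=set()
            )


class TestPrepareSplit:
    def _toy(self):
        # 1 feature-rich block; cell c0 has only 50 total counts
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 10, (55, 120)).astype(float)
        counts[0] = 0.0
        counts[0, :25] = 2.0  # 50 counts over 25 features
        batch = np.array(["ref"] * 30 + ["qry"] * 25, object)
        label = np.array(["big"] * 25 + ["small"] * 5 + ["big"] * 25, object)
        return _raw(counts, batch, label)

    def test_low_count_cell_removed(self):
        ds = prepare_split(self._toy(), query_batches={"qry"})
        assert "c0" not in ds.reference.cell_ids
        assert ds.provenance["cells_removed_qc"] == 1

    def test_small_label_removed_from_both_halves(self):
        counts = np.ones((70, 120), float) * 3
        batch = np.array(["ref"] * 35 + ["qry"] * 35, object)
        label = np.array(
            ["big"] * 20 + ["small"] * 15 + ["big"] * 25 + ["small"] * 10, object
        )
        ds = prepare_split(
            _raw(counts, batch, label), query_batches={"qry"}, min_label_cells=20
        )
        assert "small" not in set(ds.reference.label)
        assert "small" not in set(ds.query.label)
        assert ds.provenance["cells_removed_small_labels_reference"] == 15
        assert ds.provenance["cells_removed_small_labels_query"] == 10

    def test_unseen_removed_from_reference_only(self):
        counts = np.ones((60, 120), float) * 3
        batch = np.array(["ref"] * 30 + ["qry"] * 30, object)
        label = np.array(["a"] * 20 + ["Rare"] * 10 + ["a"] * 10 + ["Rare"] * 20,
                         object)
        ds = prepare_split(
            _raw(counts, batch, label),
            query_batches={"qry"},
            unseen_labels={"Rare"},
            min_label_cells=5,
        )
        assert "Rare" not in set(ds.reference.label)
        assert (ds.query.label == "Rare").sum() == 20
        assert ds.provenance["cells_removed_unseen_reference"] == 10

    def test_unseen_absent_from_query_errors(self):
        with pytest.raises(ConfigurationError, match="unseen"):
            prepare_split(
                self._toy(), query_batches={"qry"}, unseen_labels={"ghost"}
            )

    def test_idempotent(self):
        ds = prepare_split(self._toy(), query_batches={"qry"})
        import warnings

        merged = ab.CellMatrix(
            counts=np.vstack([ds.reference.dense_counts(), ds.query.dense_counts()]),
            cell_ids=np.concatenate([ds.reference.cell_ids, ds.query.cell_ids]),
            feature_ids=ds.reference.feature_ids,
            batch=np.concatenate([ds.reference.batch, ds.query.batch]),
            label=np.concatenate([ds.reference.label, ds.query.label]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = prepare_split(merged, query_batches={"qry"})
        assert np.array_equal(again.reference.cell_ids, ds.reference.cell_ids)
        assert np.array_equal(again.query.cell_ids, ds.query.cell_ids)
        assert np.array_equal(again.reference.feature_ids, ds.reference.feature_ids)

    def test_provenance_counts_sum(self):
        raw = self._toy()
        ds = prepare_split(raw, query_batches={"qry"})
        p = ds.provenance
        after_qc = p["cells_in"] - p["cells_removed_qc"]
        assert (
            p["cells_reference_after_split"] + p["cells_query_after_split"]
            == after_qc
        )
        assert (
            p["cells_out_reference"]
            == p["cells_reference_after_split"]
            - p["cells_removed_small_labels_reference"]
            - p["cells_removed_unseen_reference"]
        )

    def test_feature_identity_across_halves(self):
        ds = prepare_split(self._toy(), query_batches={"qry"})
        assert np.array_equal(ds.reference.feature_ids, ds.query.feature_ids)


class TestScoreTables:
    def _table(self):
        return pd.DataFrame(
            {
                "dataset": ["d1", "d1"],
                "method": ["m1", "m1"],
                "metric": ["ilisi", "cms"],
                "category": ["batch", "batch"],
                "value": [0.5, 0.75],
            }
        )

    def test_round_trip(self, tmp_path):
        path = tmp_path / "scores.tsv"
        table = self._table()
        ab.write_scores(table, path)
        back = ab.read_scores(path)
        pd.testing.assert_frame_equal(back, table)

    def test_nan_preserved_and_flagged(self, tmp_path):
        table = self._table()
        table.loc[1, "value"] = np.nan
        path = tmp_path / "scores.tsv"
        ab.write_scores(table, path)
        with pytest.warns(UserWarning, match="missing"):
            back = ab.read_scores(path)
        assert back["value"].isna().sum() == 1

    def test_unknown_category_rejected(self, tmp_path):
        table = self._table()
        table.loc[0, "category"] = "nonsense"
        with pytest.raises(ValueError, match="categor"):
            ab.write_scores(table, tmp_path / "scores.tsv")


def test_embedding_obsm_round_trip(tmp_path, small_split, small_embedding):
    path = tmp_path / "split.h5ad"
    ds = small_split
    ab.write_split_h5ad(
        ab.SplitDataset(ds.reference, ds.query, ds.unseen_labels), path
    )
    ab.write_embedding_h5ad(path, small_embedding)
    back = ab.read_embedding_h5ad(path)
    np.testing.assert_allclose(back.ref_coords, small_embedding.ref_coords)
    np.testing.assert_allclose(back.query_coords, small_embedding.query_coords)
    np.testing.assert_allclose(
        back.pre_integration, small_embedding.pre_integration
    )
    from atlasbench.core_data import ConfigurationError

    with pytest.raises(ConfigurationError, match="obsm"):
        ab.read_embedding_h5ad(path, emb_key="missing")


def test_split_h5ad_round_trip(tmp_path, small_split):
    path = tmp_path / "split.h5ad"
    ds = small_split
    ab.write_split_h5ad(
        ab.SplitDataset(ds.reference, ds.query, ds.unseen_labels, {"seed": 7}),
        path,
    )
    ds2 = ab.read_split_h5ad(path)
    assert ds2.unseen_labels == ds.unseen_labels
    assert np.array_equal(ds2.reference.cell_ids, ds.reference.cell_ids)
    np.testing.assert_allclose(
        ds2.query.dense_counts(), ds.query.dense_counts()
    )
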