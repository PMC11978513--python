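import numpy as np
import pytest

import atlasbench as ab
from atlasbench.synthetic import BatchSpec, LabelSpec, SimConfig


def _plain_config(**kw):
    defaults = dict(
        n_features=200,
        labels=(LabelSpec("a", 50, 0.0, 0.0), LabelSpec("b", 50, 0.0, 0.0)),
        batches=(BatchSpec("r1"), BatchSpec("q1")),
        query_batches=frozenset({"q1"}),
        batch_effect_sd=0.0,
        label_noise_sd=0.0,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateCounts:
    def test_seed_determinism(self):
        a = ab.simulate_counts(_plain_config())
        b = ab.simulate_counts(_plain_config())
        np.testing.assert_array_equal(
            a.reference.dense_counts(), b.reference.dense_counts()
        )
        np.testing.assert_array_equal(a.query.dense_counts(), b.query.dense_counts())

    def test_mean_counts_match_analytic_expectation(self):
        # no DE, no batch effect, no extra noise: the expected count of gene g
        # is m_g / sum(m) * E[library]; compare empirical means at n=2,000
        cfg = _plain_config(
            labels=(LabelSpec("a", 1000, 0.0, 0.0), LabelSpec("b", 1000, 0.0, 0.0)),
            lib_sd=0.0,
        )
        rng = np.random.default_rng(cfg.seed)
        base = np.maximum(
            rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=cfg.n_features),
            1e-8,
        )
        lib = np.exp(cfg.lib_loc)
        expected_full = base / base.sum() * lib
        ds = ab.simulate_counts(cfg)
        kept = np.array(
            [int(f[4:]) for f in ds.reference.feature_ids]
        )
        expected = expected_full[kept]
        counts = np.vstack(
            [ds.reference.dense_counts(), ds.query.dense_counts()]
        )
        n = counts.shape[0]
        emp_mean = counts.mean(axis=0)
        # NB variance mu(1 + bcv^2 mu) gives the standard error of the mean
        se = np.sqrt(expected * (1 + cfg.bcv**2 * expected) / n)
        frac_within = (np.abs(emp_mean - expected) <= 3 * se + 1e-9).mean()
        assert frac_within > 0.98

    def test_depth_factor_scales_library_size(self):
        cfg = _plain_config(
            labels=(LabelSpec("a", 400, 0.0, 0.0), LabelSpec("b", 400, 0.0, 0.0)),
            batches=(
                BatchSpec("r1", depth_factor=1.0),
                BatchSpec("q1", depth_factor=0.2),
            ),
        )
        ds = ab.simulate_counts(cfg)
        med_ref = np.median(ds.reference.dense_counts().sum(axis=1))
        med_query = np.median(ds.query.dense_counts().sum(axis=1))
        assert med_query / med_ref == pytest.approx(0.2, rel=0.10)

    def test_negative_binomial_overdispersion(self):
        cfg = _plain_config(
            labels=(LabelSpec("a", 1000, 0.0, 0.0), LabelSpec("b", 1000, 0.0, 0.0)),
            bcv=0.4,
        )
        ds = ab.simulate_counts(cfg)
        x = ds.reference.dense_counts()
        mean = x.mean(axis=0)
        var = x.var(axis=0, ddof=1)
        informative = mean > 1
        assert (var[informative] >= mean[informative]).mean() > 0.95

    def test_unseen_labels_only_in_query(self):
        cfg = _plain_config(
            labels=(
                LabelSpec("a", 50, 0.1, 1.0),
                LabelSpec("b", 50, 0.1, 1.0),
                LabelSpec("Rare", 20, 0.2, 1.0),
            ),
            unseen_labels=frozenset({"Rare"}),
        )
        ds = ab.simulate_counts(cfg)
        assert "Rare" not in set(ds.reference.label)
        assert "Rare" in set(ds.query.label)

    def test_infeasible_label_errors(self):
        cfg = _plain_config(
            batches=(
                BatchSpec("r1", n_cells_factor=0.001),
                BatchSpec("q1"),
            ),
        )
        with pytest.raises(ValueError, match="0 cells"):
            ab.simulate_counts(cfg)

    def test_trajectory_labels_present(self):
        cfg = ab.splat_scenario(scale=0.3, seed=3, n_features=200)
        ds = ab.simulate_counts(cfg)
        labels = set(ds.reference.label) | set(ds.query.label)
        assert {"Progenitor", "BranchA", "Intermediate"} <= labels
        assert "Intermediate" not in set(ds.reference.label)


class TestSimulateEmbedding:
    def test_zero_batch_shift_gives_identical_batches(self):
        cfg = ab.EmbConfig(
            d=4, n_labels=2, n_batches=2, n_per_group=250, batch_shift_sd=0.0,
            seed=0,
        )
        emb, labels, batches, is_query = ab.simulate_embedding(cfg)
        coords = emb.all_coords
        a = coords[batches == "batch0"]
        b = coords[batches == "batch1"]
        # permutation test on the energy statistic: identically distributed
        # batches should not look separable
        p = _energy_pvalue(a, b, n_perm=200, seed=1)
        assert p > 0.01

    def test_far_unseen_placement(self):
        cfg = ab.EmbConfig(
            d=4, n_labels=3, n_batches=2, n_per_group=20, cluster_sd=1.5,
            unseen_labels=("u",), unseen_placement="far", seed=2,
        )
        emb, labels, batches, is_query = ab.simulate_embedding(cfg)
        coords = emb.all_coords
        u_center = coords[labels == "u"].mean(axis=0)
        for name in ("label0", "label1", "label2"):
            c = coords[labels == name].mean(axis=0)
            assert np.linalg.norm(u_center - c) >= 6 * cfg.cluster_sd * 0.8

    def test_seed_determinism(self):
        cfg = ab.EmbConfig(seed=5)
        a = ab.simulate_embedding(cfg)[0]
        b = ab.simulate_embedding(cfg)[0]
        np.testing.assert_array_equal(a.all_coords, b.all_coords)

    def test_reference_rows_first(self):
        emb, labels, batches, is_query = ab.simulate_embedding(ab.EmbConfig())
        assert not is_query[: emb.ref_coords.shape[0]].any()
        assert is_query[emb.ref_coords.shape[0] :].all()


def _energy_pvalue(a, b, n_perm=200, seed=0):
    from scipy.spatial.distance import cdist

    def stat(x, y):
        return (
            2 * cdist(x, y).mean() - cdist(x, x).mean() - cdist(y, y).mean()
        )

    rng = np.random.default_rng(seed)
    obs = stat(a, b)
    pooled = np.vstack([a, b])
    n = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        if stat(pooled[idx[:n]], pooled[idx[n:]]) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


class TestFixtureIntegrate:
    def _mean_shift_ds(self, seed=0):
        cfg = _plain_config(
            labels=(LabelSpec("a", 80, 0.2, 1.0), LabelSpec("b", 80, 0.2, 1.0)),
            batches=(BatchSpec("r1"), BatchSpec("r2"), BatchSpec("q1")),
            batch_effect_sd=0.4,
            seed=seed,
        )
        return ab.simulate_counts(cfg)

    @staticmethod
    def _centroid_spread(emb, batch):
        coords = emb.all_coords
        centroids = np.vstack(
            [coords[batch == b].mean(axis=0) for b in np.unique(batch)]
        )
        return np.linalg.norm(centroids - centroids.mean(axis=0), axis=1).mean()

    def test_full_removal_centers_batches(self):
        ds = self._mean_shift_ds()
        batch = np.concatenate([ds.reference.batch, ds.query.batch])
        spread0 = self._centroid_spread(
            ab.fixture_integrate(ds, n_pcs=5, removal=0.0), batch
        )
        spread1 = self._centroid_spread(
            ab.fixture_integrate(ds, n_pcs=5, removal=1.0), batch
        )
        assert spread1 <= 0.01 * spread0

    def test_zero_removal_is_uncorrected_pca(self):
        ds = self._mean_shift_ds()
        emb = ab.fixture_integrate(ds, n_pcs=5, removal=0.0)
        np.testing.assert_array_equal(
            emb.all_coords, emb.pre_integration
        )

    def test_duplicated_cell_maps_to_same_point(self):
        ds = self._mean_shift_ds()
        # make one query cell an exact copy of a reference cell
        q = ds.query.dense_counts().copy()
        q[0] = ds.reference.dense_counts()[0]
        query = ab.CellMatrix(
            counts=q,
            cell_ids=ds.query.cell_ids,
            feature_ids=ds.query.feature_ids,
            batch=ds.query.batch,
            label=ds.query.label,
        )
        ds2 = ab.SplitDataset(ds.reference, query, ds.unseen_labels)
        emb = ab.fixture_integrate(ds2, n_pcs=5, removal=0.0)
        np.testing.assert_allclose(
            emb.query_coords[0], emb.ref_coords[0], atol=1e-9
        )

    def test_removal_monotone_in_centroid_separation(self):
        ds = self._mean_shift_ds(seed=3)
        batch = np.concatenate([ds.reference.batch, ds.query.batch])
        spreads = [
            self._centroid_spread(
                ab.fixture_integrate(ds, n_pcs=5, removal=r), batch
            )
            for r in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(s2 <= s1 + 1e-9 for s1, s2 in zip(spreads, spreads[1:]))
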