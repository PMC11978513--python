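import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasbench.core_data import CATEGORIES
from atlasbench.scoring import (
    BASELINE_METHODS,
    CATEGORY_WEIGHTS,
    aggregate,
    overall_score,
    profile_metrics,
    rank_methods,
    scale_scores,
    standardize,
)


def _scaled_from_categories(values):
    """One metric per category with the given scaled value."""
    return pd.DataFrame(
        {
            "dataset": "d",
            "method": "m",
            "metric": ["ilisi", "bnmi", "cell_distance", "f1_macro", "milo"],
            "category": list(CATEGORIES),
            "scaled": list(values),
        }
    )


class TestAggregate:
    def test_weights_sum_to_one(self):
        assert sum(CATEGORY_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-15)

    def test_all_ones_gives_one(self):
        assert aggregate(_scaled_from_categories([1] * 5)).overall == pytest.approx(
            1.0, abs=1e-12
        )

    def test_batch_only_gives_quarter(self):
        s = aggregate(_scaled_from_categories([1, 0, 0, 0, 0]))
        assert s.overall == pytest.approx(0.25, abs=1e-12)

    def test_hand_evaluated_example(self):
        s = aggregate(_scaled_from_categories([0.8, 0.6, 0.9, 0.3, 0.6]))
        expected = 0.25 * 0.8 + 0.25 * 0.6 + (0.9 + 0.3 + 0.6) / 6
        assert s.overall == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.65, abs=1e-12)

    def test_random_vectors_match_printed_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v = rng.uniform(-0.5, 1.5, 5)
            s = aggregate(_scaled_from_categories(v))
            hand = 0.5 * (v[0] / 2 + v[1] / 2) + 0.5 * (
                v[2] / 3 + v[3] / 3 + v[4] / 3
            )
            assert s.overall == pytest.approx(hand, abs=1e-12)

    def test_overall_recomputable_from_fields(self):
        s = aggregate(_scaled_from_categories([0.1, 0.9, 0.4, 0.2, 0.7]))
        cats = {
            "batch": s.int_batch,
            "bio": s.int_bio,
            "mapping": s.mapping,
            "classification": s.classification,
            "unseen": s.unseen,
        }
        assert s.overall == pytest.approx(overall_score(cats), abs=1e-15)

    def test_missing_category_errors(self):
        table = _scaled_from_categories([1] * 5).iloc[:4]
        with pytest.raises(ValueError, match="unseen"):
            aggregate(table)

    def test_order_within_category_irrelevant(self):
        t = _scaled_from_categories([0.3, 0.5, 0.2, 0.9, 0.4])
        extra = pd.DataFrame(
            {
                "dataset": "d",
                "method": "m",
                "metric": ["cms", "clisi"],
                "category": ["batch", "bio"],
                "scaled": [0.7, 0.1],
            }
        )
        a = aggregate(pd.concat([t, extra]))
        b = aggregate(pd.concat([extra.iloc[::-1], t.iloc[::-1]]))
        assert a.overall == pytest.approx(b.overall, abs=1e-15)


@given(
    st.lists(
        st.floats(-1.0, 2.0, allow_nan=False, allow_infinity=False),
        min_size=5, max_size=5,
    )
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_overall_formula_property(values):
    """aggregate always equals the printed weighted-mean formula."""
    s = aggregate(_scaled_from_categories(values))
    v = values
    hand = 0.5 * (v[0] / 2 + v[1] / 2) + 0.5 * (v[2] / 3 + v[3] / 3 + v[4] / 3)
    assert s.overall == pytest.approx(hand, abs=1e-12)


@given(
    st.floats(0.01, 1.0), st.floats(-0.5, 0.5),
    st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4, unique=True),
)
@settings(deadline=None, max_examples=25, derandomize=True)
def test_scaling_affine_equivariance_property(scale, shift, base_vals):
    """Scaled scores are invariant under a shared affine map of raw scores."""
    base = pd.DataFrame(
        {
            "dataset": "d", "method": list(BASELINE_METHODS),
            "metric": "m", "category": "batch", "value": base_vals,
        }
    )
    raw = pd.DataFrame(
        {
            "dataset": ["d"], "method": ["x"], "metric": "m",
            "category": "batch", "value": [0.42],
        }
    )
    out1 = scale_scores(raw, base)["scaled"]
    base2, raw2 = base.copy(), raw.copy()
    base2["value"] = base2["value"] * scale + shift
    raw2["value"] = raw2["value"] * scale + shift
    out2 = scale_scores(raw2, base2)["scaled"]
    np.testing.assert_allclose(out1, out2, atol=1e-9)


class TestScaleScores:
    def _tables(self):
        base = pd.DataFrame(
            {
                "dataset": "d",
                "method": list(BASELINE_METHODS),
                "metric": "ilisi",
                "category": "batch",
                "value": [0.2, 0.4, 0.5, 0.9],
            }
        )
        raw = pd.DataFrame(
            {
                "dataset": ["d"] * 3,
                "method": ["m1", "m2", "m3"],
                "metric": "ilisi",
                "category": "batch",
                "value": [0.9, 0.2, 0.05],
            }
        )
        return raw, base

    def test_endpoints_map_to_unit_interval(self):
        raw, base = self._tables()
        out = scale_scores(raw, base)
        assert out.loc[0, "scaled"] == pytest.approx(1.0)   # equals max baseline
        assert out.loc[1, "scaled"] == pytest.approx(0.0)   # equals min baseline

    def test_out_of_range_preserved_unclipped(self):
        raw, base = self._tables()
        out = scale_scores(raw, base)
        assert out.loc[2, "scaled"] == pytest.approx(
            (0.05 - 0.2) / 0.7, abs=1e-12
        )
        assert out.loc[2, "scaled"] == pytest.approx(-0.2143, abs=1e-4)
        raw2 = raw.copy()
        raw2.loc[0, "value"] = 0.95
        assert scale_scores(raw2, base).loc[0, "scaled"] > 1.0

    def test_affine_equivariance(self):
        raw, base = self._tables()
        out1 = scale_scores(raw, base)["scaled"]
        raw2, base2 = raw.copy(), base.copy()
        raw2["value"] += 0.05
        base2["value"] += 0.05
        out2 = scale_scores(raw2, base2)["scaled"]
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    def test_degenerate_baseline_range_yields_missing(self):
        raw, base = self._tables()
        base["value"] = 0.5
        with pytest.warns(UserWarning, match="zero"):
            out = scale_scores(raw, base)
        assert out["scaled"].isna().all()


class TestRankMethods:
    def _summaries(self, scores):
        rows = []
        for (ds, m), v in scores.items():
            rows.append({"dataset": ds, "method": m, "overall": v})
        return pd.DataFrame(rows)

    def test_descending_ranks(self):
        summaries = self._summaries(
            {("d", "a"): 0.9, ("d", "b"): 0.5, ("d", "c"): 0.1}
        )
        out = rank_methods(summaries)
        assert list(out["method"]) == ["a", "b", "c"]
        assert list(out["mean_rank"]) == [1.0, 2.0, 3.0]

    def test_ties_get_average_rank(self):
        out = rank_methods(self._summaries({("d", "a"): 0.5, ("d", "b"): 0.5}))
        assert list(out["mean_rank"]) == [1.5, 1.5]

    def test_cross_dataset_matches_sort_oracle(self):
        scores = {
            ("d1", "a"): 0.9, ("d1", "b"): 0.2, ("d1", "c"): 0.5,
            ("d2", "a"): 0.1, ("d2", "b"): 0.8, ("d2", "c"): 0.5,
        }
        out = rank_methods(self._summaries(scores)).set_index("method")
        # oracle: sort within each dataset
        expect = {"a": np.mean([1, 3]), "b": np.mean([3, 1]), "c": np.mean([2, 2])}
        for m, r in expect.items():
            assert out.loc[m, "mean_rank"] == pytest.approx(r)

    def test_invariant_to_monotone_transform(self):
        summaries = self._summaries(
            {("d1", "a"): 0.9, ("d1", "b"): 0.2, ("d2", "a"): 0.4, ("d2", "b"): 0.6}
        )
        out1 = rank_methods(summaries)
        summaries2 = summaries.copy()
        summaries2["overall"] = np.exp(5 * summaries2["overall"])
        out2 = rank_methods(summaries2)
        pd.testing.assert_frame_equal(out1, out2)


class TestStandardize:
    def _frame(self, values, group="g"):
        return pd.DataFrame({"group": group, "scaled": values})

    def test_simple_triplet(self):
        z = standardize(self._frame([1.0, 2.0, 3.0]), ["group"])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_group_maps_to_zero(self):
        z = standardize(self._frame([2.0, 2.0, 2.0]), ["group"])
        np.testing.assert_allclose(z, 0.0)

    def test_matches_formula_on_random_groups(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 10),
                "scaled": rng.normal(0, 2, 20),
            }
        )
        z = standardize(df, ["group"])
        for g in "ab":
            v = df[df["group"] == g]["scaled"]
            np.testing.assert_allclose(
                z[df["group"] == g], (v - v.mean()) / v.std(ddof=1), atol=1e-12
            )


class TestProfileMetrics:
    def _scores(self):
        rows = []
        rng = np.random.default_rng(2)
        for nf in (100, 500, 1000):
            for rep in range(3):
                rows.append(("const", 0.5, nf, "random"))
                rows.append(("linear", nf / 1000, nf, "ordered"))
                rows.append(("noisy", rng.uniform(), nf, "random"))
                rows.append(("noisy", rng.uniform(), nf, "ordered"))
        return pd.DataFrame(
            rows, columns=["metric", "value", "n_features", "set_type"]
        )

    def test_constant_metric_has_zero_range(self):
        with pytest.warns(UserWarning):
            out = profile_metrics(self._scores())
        profile = out["profile"].set_index("metric")
        assert profile.loc["const", "observed_range"] == 0.0

    def test_linear_metric_perfectly_correlated(self):
        with pytest.warns(UserWarning):
            out = profile_metrics(self._scores())
        profile = out["profile"].set_index("metric")
        assert profile.loc["linear", "corr_n_features"] == pytest.approx(1.0)

    def test_inter_metric_correlations_match_pearson_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for i, nf in enumerate(range(5, 25)):
            for metric in "abcde":
                rows.append((metric, rng.uniform(), nf, "random"))
        df = pd.DataFrame(
            rows, columns=["metric", "value", "n_features", "set_type"]
        )
        out = profile_metrics(df)
        corr = out["inter_metric"]
        wide = df.pivot_table(index="n_features", columns="metric",
                              values="value")
        for a in "abcde":
            for b in "abcde":
                x, y = wide[a].to_numpy(), wide[b].to_numpy()
                expected = np.corrcoef(x, y)[0, 1]
                assert corr.loc[a, b] == pytest.approx(expected, abs=1e-12)
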