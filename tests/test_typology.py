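"""Clustering, ordination, permutation testing and post-hoc statistics."""

import numpy as np
import pandas as pd
import pytest

from pamdsi import typology as ty


def blob_features(n_per=8, sep=10.0, sigma=1.0, seed=0, p=3):
    rng = np.random.default_rng(seed)
    centers = sep * np.arange(4)[:, None] * np.ones(p)
    X = np.vstack([c + sigma * rng.standard_normal((n_per, p)) for c in centers])
    labels = np.repeat(np.arange(4), n_per)
    idx = [f"G{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx), labels


class TestWardCluster:
    def test_separated_blobs_recovered_exactly(self):
        X, truth = blob_features(sigma=0.1 * 10.0)
        clusters = ty.ward_cluster(X, 4)
        # identical partition up to relabeling
        df = pd.DataFrame({"truth": truth, "cluster": clusters})
        assert (df.groupby("truth")["cluster"].nunique() == 1).all()
        assert df["cluster"].nunique() == 4

    def test_k_equals_n_gives_singletons(self):
        X, _ = blob_features(n_per=2)
        clusters = ty.ward_cluster(X, len(X))
        assert len(np.unique(clusters)) == len(X)

    def test_k_above_n_rejected(self):
        X, _ = blob_features(n_per=1)
        with pytest.raises(ValueError):
            ty.ward_cluster(X, len(X) + 1)

    def test_row_permutation_consistency(self):
        X, _ = blob_features()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(X))
        a = ty.ward_cluster(X, 4)
        b = ty.ward_cluster(X.iloc[perm], 4)
        # same partition: co-membership matrices agree under the permutation
        same_a = a[perm][:, None] == a[perm][None, :]
        same_b = b[:, None] == b[None, :]
        assert (same_a == same_b).all()


class TestLabelClasses:
    def test_sorted_by_mean_dsi(self):
        clusters = np.array([1, 2, 3, 4])
        dsi = pd.Series([0.7, 0.2, 0.5, 0.3], index=list("abcd"))
        out = ty.label_classes(clusters, dsi)
        assert list(out["class_label"]) == ["HS", "MR", "S", "MS"]

    def test_true_classes_recovered_in_order(self, default_run):
        assign = default_run["assignment"]
        means = assign.groupby("class_label")["class_mean_dsi"].first()
        assert means["MR"] < means["MS"] < means["S"] < means["HS"]

    def test_tie_broken_by_size_with_warning(self):
        clusters = np.array([1, 1, 2, 2, 2, 3, 4])
        dsi = pd.Series([0.5, 0.5, 0.5, 0.5, 0.5, 0.1, 0.9],
                        index=[f"g{i}" for i in range(7)])
        with pytest.warns(UserWarning, match="tie"):
            out = ty.label_classes(clusters, dsi)
        # larger tied cluster first (lower label)
        assert out.loc["g2", "class_label"] == "MS"
        assert out.loc["g0", "class_label"] == "S"

    def test_wrong_cluster_count_rejected(self):
        with pytest.raises(ValueError):
            ty.label_classes(np.array([1, 1, 2]), pd.Series([0.1, 0.2, 0.3]))


class TestPCA:
    def test_perfectly_correlated_features_one_axis(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = ty.pca(X)
        assert res.explained[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, default_run):
        res = ty.pca(default_run["features"])
        assert res.explained.sum() == pytest.approx(1.0)
        assert (res.explained >= 0).all()

    def test_loadings_orthonormal(self, default_run):
        res = ty.pca(default_run["features"])
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_contribution_threshold_and_totals(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((30, 10)))
        res = ty.pca(X)
        assert res.threshold == pytest.approx(10.0)  # 100 / p
        assert np.allclose(res.contributions.sum(axis=0), 100.0)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.standard_normal(10),
                          "b": rng.standard_normal(10),
                          "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            res = ty.pca(X)
        assert "c" not in res.loadings.index


class TestPermutationTest:
    def test_perfect_separation_attains_minimum_p(self):
        X, labels = blob_features(sigma=0.01)
        res = ty.monte_carlo_inertia_test(X, labels, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.statistic > 0.99

    def test_identical_class_means_give_small_statistic(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((200, 3)))
        labels = np.repeat([0, 1], 100)
        res = ty.monte_carlo_inertia_test(X, labels, n_permutations=199, seed=0)
        assert res.statistic < 0.05

    def test_statistic_in_unit_interval(self, default_run):
        res = ty.monte_carlo_inertia_test(
            default_run["features"],
            default_run["assignment"]["class_label"].to_numpy(),
            n_permutations=199,
            seed=0,
        )
        assert 0 <= res.statistic <= 1
        assert res.p_value == pytest.approx(1 / 200)  # classes are real

    def test_single_class_rejected(self):
        X, _ = blob_features()
        with pytest.raises(ValueError):
            ty.monte_carlo_inertia_test(X, np.zeros(len(X)), 199, 0)

    def test_too_few_permutations_rejected(self):
        X, labels = blob_features()
        with pytest.raises(ValueError):
            ty.monte_carlo_inertia_test(X, labels, n_permutations=50)


class TestLSD:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        vals = np.tile(rng.standard_normal(10), 2)
        labels = np.repeat(["a", "b"], 10)
        out = ty.lsd_groups(vals, labels)
        assert out["letters"].nunique() == 1

    def test_widely_separated_groups_differ(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        vals = np.concatenate([x, x + 10.0])  # 10 pooled SDs apart
        labels = np.repeat(["lo", "hi"], 12)
        out = ty.lsd_groups(vals, labels)
        letters = dict(zip(out["group"], out["letters"]))
        assert set(letters["lo"]).isdisjoint(letters["hi"])

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(m, 1, 8) for m in (0, 1, 5)])
        labels = np.repeat(["a", "b", "c"], 8)
        perm = rng.permutation(len(vals))
        a = ty.lsd_groups(vals, labels)
        b = ty.lsd_groups(vals[perm], labels[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_class_dsi_all_distinct(self, default_run):
        dsi = default_run["dsi"]["dsi"]
        labels = default_run["assignment"]["class_label"]
        out = ty.lsd_groups(dsi.to_numpy(), labels.to_numpy())
        assert out["letters"].nunique() == 4  # all four typologies separate

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ty.lsd_groups(np.repeat([1.0, 2.0], 5), np.repeat(["a", "b"], 5))


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        res = ty.pearson_matrix(pd.DataFrame({"x": x, "y": 2 * x}))
        assert res.r.loc["x", "y"] == pytest.approx(1.0)
        assert res.stars.loc["x", "y"] == "***"

    def test_unit_diagonal(self):
        rng = np.random.default_rng(0)
        res = ty.pearson_matrix(pd.DataFrame(rng.standard_normal((20, 3))))
        assert np.allclose(np.diag(res.r), 1.0)

    def test_constant_variable_undefined(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.standard_normal(10), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            res = ty.pearson_matrix(df)
        assert np.isnan(res.r.loc["x", "c"])

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError):
            ty.pearson_matrix(df)
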