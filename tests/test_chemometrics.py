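"""Pareto scaling, NIPALS PLS-DA/OPLS-DA, validation statistics and VIP."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from seasonfuse.chemometrics import (
    cross_validate,
    fit_oplsda,
    fit_plsda,
    hierarchical_cluster,
    most_scattered_season,
    one_hot,
    pareto_scale,
    permutation_test,
    top_k_vip,
    vip_scores,
)


def two_class_data(n=20, p=10, sep=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n, p))
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    x[labels == "b", 0] += sep
    return x, labels


def four_class_data(n_per=6, p=30, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    classes = ["summer", "autumn", "winter", "spring"]
    x = rng.normal(0, 1, (n_per * 4, p))
    labels = np.repeat(classes, n_per)
    for k, cls in enumerate(classes):
        x[labels == cls, k] += sep
    return x, labels


class TestParetoScale:
    def test_hand_computed_column(self):
        out = pareto_scale(np.array([[0.0], [2.0]]))
        sd = np.sqrt(2)  # ddof=1
        np.testing.assert_allclose(out[:, 0], [-1 / np.sqrt(sd), 1 / np.sqrt(sd)],
                                   atol=1e-9)
        np.testing.assert_allclose(out[:, 0], [-0.8409, 0.8409], atol=1e-4)

    def test_columns_centered(self):
        rng = np.random.default_rng(1)
        out = pareto_scale(rng.lognormal(2, 1, (10, 5)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_constant_column_maps_to_zero(self):
        out = pareto_scale(np.array([[1.0, 3.0], [1.0, 4.0], [1.0, 5.0]]))
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_dataframe_round_trip(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 1.0]], columns=["a", "b"])
        out = pareto_scale(df)
        assert isinstance(out, pd.DataFrame)
        assert out.columns.tolist() == ["a", "b"]


class TestFitPlsda:
    def test_separable_classes_separate_on_first_component(self):
        x, labels = two_class_data()
        model = fit_plsda(x, labels, 1)
        t = model.scores[:, 0]
        assert max(t[labels == "a"]) < min(t[labels == "b"]) or \
               min(t[labels == "a"]) > max(t[labels == "b"])

    def test_zero_components_rejected(self):
        x, labels = two_class_data()
        with pytest.raises(ValueError):
            fit_plsda(x, labels, 0)

    def test_single_class_rejected(self):
        x, _ = two_class_data()
        with pytest.raises(ValueError):
            fit_plsda(x, ["a"] * len(x), 1)

    def test_score_orthogonality(self):
        x, labels = four_class_data()
        model = fit_plsda(x, labels, 4)
        t = model.scores
        gram = t.T @ t
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_first_weight_equals_xty_direction_single_response(self):
        """For a single centered response and A=1, the NIPALS weight is the
        normalized X'y vector (the PLS1 eigen-direction)."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (15, 8))
        labels = np.array(["a", "b"] * 7 + ["a"])
        model = fit_plsda(x, labels, 1)
        y, _ = one_hot(labels)
        yc = (y - y.mean(axis=0))[:, 1]
        xc = x - x.mean(axis=0)
        expected = xc.T @ yc
        expected /= np.linalg.norm(expected)
        got = model.weights[:, 0]
        assert min(np.linalg.norm(got - expected),
                   np.linalg.norm(got + expected)) < 1e-8

    def test_deflation_conserves_sum_of_squares(self):
        x, labels = four_class_data()
        xc = x - x.mean(axis=0)
        model = fit_plsda(x, labels, 4)
        explained = sum(np.sum(np.outer(model.scores[:, a], model.loadings[:, a]) ** 2)
                        for a in range(4))
        residual = np.sum(xc ** 2) * (1 - model.r2x)
        assert explained + residual == pytest.approx(np.sum(xc ** 2), rel=1e-6)

    def test_r2x_nondecreasing_in_components(self):
        x, labels = four_class_data()
        r2x = [fit_plsda(x, labels, a).r2x for a in (1, 2, 3)]
        assert r2x == sorted(r2x)

    def test_predictions_match_sklearn_pls2(self):
        """Cross-check against an independent PLS implementation: identical
        centered one-hot regression setup, identical fitted Y."""
        x, labels = four_class_data()
        y, _ = one_hot(labels)
        ours = fit_plsda(x, labels, 3)
        ref = PLSRegression(n_components=3, scale=False,
                            tol=1e-12, max_iter=2000).fit(x, y)
        np.testing.assert_allclose(ours.predict_y(x), ref.predict(x), atol=1e-6)


class TestFitOplsda:
    def test_predictive_aligns_with_class_direction(self):
        rng = np.random.default_rng(3)
        n = 24
        labels = np.array(["a"] * 12 + ["b"] * 12)
        class_dir = np.zeros(10); class_dir[0] = 1.0
        orth_dir = np.zeros(10); orth_dir[1] = 1.0
        y_sign = np.where(labels == "b", 1.0, -1.0)
        x = (np.outer(y_sign, class_dir) * 2
             + np.outer(rng.normal(0, 3, n), orth_dir)
             + rng.normal(0, 0.1, (n, 10)))
        model = fit_oplsda(x, labels, 1, 1)
        w = model.weights[:, 0]
        cosine = abs(w @ class_dir) / np.linalg.norm(w)
        assert cosine > 0.95

    def test_zero_orth_reduces_to_plsda(self):
        x, labels = two_class_data()
        op = fit_oplsda(x, labels, 1, 0)
        pls = fit_plsda(x, labels, 1)
        np.testing.assert_allclose(op.predict_y(x), pls.predict_y(x), atol=1e-6)

    def test_predictive_and_orthogonal_scores_uncorrelated(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (20, 15))
        labels = np.array(["a", "b"] * 10)
        model = fit_oplsda(x, labels, 1, 2)
        for a in range(model.orth_scores.shape[1]):
            r = np.corrcoef(model.scores[:, 0], model.orth_scores[:, a])[0, 1]
            assert abs(r) < 1e-6

    def test_multiclass_rejected(self):
        x, labels = four_class_data()
        with pytest.raises(ValueError):
            fit_oplsda(x, labels, 1, 1)


class TestCrossValidate:
    def test_q2_not_above_r2y(self):
        x, labels = four_class_data(sep=2.0)
        _, r2y, q2 = cross_validate(x, labels, 2, n_folds=3, seed=0)
        assert q2 <= r2y

    def test_separable_data_high_q2(self):
        x, labels = two_class_data(n=20, sep=8.0)
        _, _, q2 = cross_validate(x, labels, 1, n_folds=5, seed=0)
        assert q2 > 0.9

    def test_noise_labels_nonpositive_q2_in_expectation(self):
        rng = np.random.default_rng(5)
        q2s = []
        for seed in range(20):
            x = rng.normal(0, 1, (16, 10))
            labels = np.array(["a", "b"] * 8)
            q2s.append(cross_validate(x, labels, 2, n_folds=4, seed=seed)[2])
        assert np.mean(q2s) < 0

    def test_fold_exceeding_class_size_rejected(self):
        x, labels = four_class_data(n_per=4)
        with pytest.raises(ValueError, match="class size"):
            cross_validate(x, labels, 2, n_folds=7)


class TestPermutationTest:
    def test_count_and_reproducibility(self):
        x, labels = four_class_data(sep=1.0)
        res1 = permutation_test(x, labels, 2, n_permutations=25, seed=9, n_folds=3)
        res2 = permutation_test(x, labels, 2, n_permutations=25, seed=9, n_folds=3)
        assert len(res1.permuted) == 25
        pd.testing.assert_frame_equal(res1.permuted, res2.permuted)
        assert res1.q2_intercept == res2.q2_intercept

    def test_informative_data_flagged_valid(self):
        x, labels = four_class_data(sep=5.0, seed=42)
        res = permutation_test(x, labels, 2, n_permutations=30, seed=42, n_folds=3)
        assert res.valid
        assert res.q2_intercept < 0

    def test_null_data_rarely_flagged_valid(self):
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(0, 1, (16, 12))
            labels = np.array(["a", "b", "c", "d"] * 4)
            res = permutation_test(x, labels, 2, n_permutations=20,
                                   seed=seed, n_folds=2)
            flags.append(res.valid)
        assert np.mean(flags) <= 0.1


class TestVip:
    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (12, 1))
        labels = np.array(["a", "b"] * 6)
        table = vip_scores(fit_plsda(x, labels, 1))
        np.testing.assert_allclose(table.vip, 1.0, atol=1e-12)

    def test_equal_weights_give_unit_vip(self):
        # Two identical informative variables: symmetric weights, VIP = 1 each.
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 14)
        labels = np.array(["a", "b"] * 7)
        base[labels == "b"] += 3
        x = np.column_stack([base, base])
        table = vip_scores(fit_plsda(x, labels, 1))
        np.testing.assert_allclose(table.vip, 1.0, atol=1e-8)

    def test_mean_squared_vip_is_one(self):
        x, labels = four_class_data()
        for a in (1, 2, 3):
            table = vip_scores(fit_plsda(x, labels, a))
            assert np.mean(table.vip ** 2) == pytest.approx(1.0, abs=1e-8)
            assert np.sum(table.vip ** 2) == pytest.approx(x.shape[1], abs=1e-6)

    def test_ranks_are_descending_permutation(self):
        x, labels = four_class_data()
        table = vip_scores(fit_plsda(x, labels, 2))
        assert sorted(table["rank"]) == list(range(1, x.shape[1] + 1))
        best = table.loc[table["rank"] == 1, "vip"].iloc[0]
        assert best == table.vip.max()


class TestTopKVip:
    def _table(self, vips):
        return pd.DataFrame({"variable_id": [f"v{i}" for i in range(len(vips))],
                             "vip": vips,
                             "rank": np.argsort(np.argsort(-np.array(vips))) + 1})

    def test_default_k_is_fifteen(self):
        rng = np.random.default_rng(8)
        table = self._table(rng.uniform(0, 2, 450))
        assert len(top_k_vip(table)) == 15

    def test_k_one_is_argmax(self):
        table = self._table([0.5, 2.0, 1.0])
        assert top_k_vip(table, 1).variable_id.tolist() == ["v1"]

    def test_ties_broken_by_input_order(self):
        table = self._table([1.0, 1.0, 1.0, 1.0])
        assert top_k_vip(table, 3).variable_id.tolist() == ["v0", "v1", "v2"]

    def test_k_exceeding_p_warns_and_returns_all(self):
        table = self._table([1.0, 2.0])
        with pytest.warns(UserWarning):
            out = top_k_vip(table, 5)
        assert len(out) == 2


class TestHierarchicalCluster:
    def test_duplicates_merge_at_zero_height(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        linkage = hierarchical_cluster(m)
        assert linkage[0, 2] == pytest.approx(0.0)
        assert set(linkage[0, :2].astype(int)) == {0, 1}

    def test_collinear_points_single_linkage(self):
        m = np.array([[0.0], [1.0], [10.0]])
        linkage = hierarchical_cluster(m, method="single")
        assert set(linkage[0, :2].astype(int)) == {0, 1}
        assert linkage[0, 2] == pytest.approx(1.0)

    def test_merge_count(self):
        rng = np.random.default_rng(9)
        linkage = hierarchical_cluster(rng.normal(0, 1, (10, 3)))
        assert linkage.shape[0] == 9

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.eye(3), method="no-such-linkage")


class TestMostScatteredSeason:
    def test_displaced_spread_group_wins(self):
        rng = np.random.default_rng(10)
        tight = rng.normal(0, 0.1, (18, 2))
        scattered = rng.normal(5, 2.0, (6, 2))
        scores = np.vstack([tight, scattered])
        labels = np.array(["rest"] * 18 + ["far"] * 6)
        assert most_scattered_season(scores, labels) == "far"
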