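"""Detection, combination, vectorization, clustering, LMNN, CV, stability."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from shollkit.analysis import (
    LMNN,
    classify_with_cv,
    combine_distances,
    detection_rate,
    feature_table,
    hierarchical_cluster,
    learn_metric,
    score_ball,
    stability_probe,
    vectorize,
)
from shollkit.metrics import DistanceMatrix
from shollkit.synthetic import generate_neuron

from .conftest import small_params


def euclid_matrix(points, labels=None):
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    M = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    ids = tuple(f"p{i}" for i in range(len(pts)))
    return DistanceMatrix(ids, M, "toy"), ids


class TestDetection:
    def test_one_dimensional_toy_is_75(self):
        D, ids = euclid_matrix([0, 1, 2, 10, 3, 4])
        labels = ["A", "A", "A", "A", "B", "B"]
        res = detection_rate(D, labels, "A")
        assert res.rate == pytest.approx(75.0)

    def test_witness_rescoring_reproduces_rate(self):
        rng = np.random.default_rng(0)
        D, ids = euclid_matrix(rng.normal(size=(20, 3)))
        labels = ["A"] * 12 + ["B"] * 8
        for lab in ("A", "B"):
            res = detection_rate(D, labels, lab)
            assert score_ball(D, labels, lab, res.center_id, res.radius) == pytest.approx(
                res.rate
            )

    def test_single_class_is_100(self):
        D, _ = euclid_matrix([0, 1, 5])
        assert detection_rate(D, ["A", "A", "A"], "A").rate == 100.0

    def test_separated_clusters_both_100(self):
        rng = np.random.default_rng(1)
        pts = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(50, 0.1, 10)])
        D, _ = euclid_matrix(pts)
        labels = ["A"] * 10 + ["B"] * 10
        assert detection_rate(D, labels, "A").rate == 100.0
        assert detection_rate(D, labels, "B").rate == 100.0

    def test_unknown_label_rejected(self):
        D, _ = euclid_matrix([0, 1])
        with pytest.raises(ValueError, match="not present"):
            detection_rate(D, ["A", "A"], "Z")

    def test_labels_accepted_as_mapping(self):
        D, ids = euclid_matrix([0, 1, 5, 6])
        table = dict(zip(ids, ["A", "A", "B", "B"]))
        assert detection_rate(D, table, "B").rate == 100.0


class TestCombine:
    @staticmethod
    def _pair():
        # separating matrix: two tight label blobs far apart
        D1, ids = euclid_matrix([0.0, 0.1, 10.0, 10.1])
        const = DistanceMatrix(D1.ids, 1 - np.eye(4), "const")
        labels = ["A", "A", "B", "B"]
        return D1, const, labels

    def test_separating_matrix_takes_all_weight(self):
        D1, const, labels = self._pair()
        res = combine_distances([D1, const], labels)
        assert res.weights == (1.0, 0.0)

    def test_single_matrix_weight_one(self):
        D1, _, labels = self._pair()
        assert combine_distances([D1], labels).weights == (1.0,)

    def test_argmax_contract_rescan(self):
        D1, const, labels = self._pair()
        res = combine_distances([D1, const], labels, grid_step=0.25)
        iu = np.triu_indices(4, k=1)
        y = np.array(labels)
        same = (y[:, None] == y[None, :])[iu]

        def objective(alpha):
            mats = []
            for m in (D1, const):
                off = m.matrix[iu]
                mats.append(m.matrix / off.mean())
            comb = alpha[0] * mats[0] + alpha[1] * mats[1]
            offc = comb[iu]
            return offc[~same].mean() / offc[same].mean()

        for a in np.arange(0, 1.25, 0.25):
            assert res.objective >= objective((a, 1 - a)) - 1e-12

    def test_objective_invariant_to_matrix_rescaling(self):
        D1, const, labels = self._pair()
        scaled = DistanceMatrix(D1.ids, D1.matrix * 37.0, "scaled")
        a = combine_distances([D1, const], labels)
        b = combine_distances([scaled, const], labels)
        assert a.objective == pytest.approx(b.objective)
        assert a.weights == b.weights

    def test_single_class_signaled(self):
        D1, _, _ = self._pair()
        with pytest.raises(ValueError, match="single class"):
            combine_distances([D1], ["A"] * 4)


class TestVectorize:
    def test_t1_wiring_value_at_1_feature(self, toys):
        feats = vectorize(toys["t1"])
        assert feats["wiring_value_at_1"] == pytest.approx(1 + 2 * np.sqrt(2))
        assert len(feats) == 24

    def test_constant_function_summaries(self, toys):
        # T1 leaf index is constant 2 -> (integral, max, argmax, value@1)
        feats = vectorize(toys["t1"], descriptors=("leaf_index",))
        assert feats["leaf_index_integral"] == pytest.approx(2.0)
        assert feats["leaf_index_max"] == 2.0
        assert feats["leaf_index_argmax"] == 0.0
        assert feats["leaf_index_value_at_1"] == 2.0

    def test_identical_neurons_zscore_to_zero(self, toys):
        df = feature_table({"a": toys["t1"], "b": toys["t1"], "c": toys["t1"]})
        np.testing.assert_allclose(df.to_numpy(), 0.0, atol=1e-12)


class TestHierarchicalCluster:
    def test_two_points_single_merge_at_distance(self):
        D, _ = euclid_matrix([0.0, 3.0])
        res = hierarchical_cluster(D, linkage="single")
        assert res.merge_tree.shape == (1, 4)
        assert res.merge_tree[0, 2] == pytest.approx(3.0)

    def test_three_point_single_linkage_heights(self):
        # mutual distances 1, 1, 10: both merges at height 1 (Lance-Williams)
        M = np.array([[0, 1, 10], [1, 0, 1], [10, 1, 0]], dtype=float)
        D = DistanceMatrix(("a", "b", "c"), M, "toy")
        res = hierarchical_cluster(D, linkage="single")
        np.testing.assert_allclose(res.merge_tree[:, 2], [1.0, 1.0])

    def test_heights_nondecreasing_all_linkages(self):
        rng = np.random.default_rng(5)
        D, _ = euclid_matrix(rng.normal(size=(12, 4)))
        for linkage in ("single", "complete", "average", "ward"):
            h = hierarchical_cluster(D, linkage=linkage).merge_tree[:, 2]
            assert np.all(np.diff(h) >= -1e-12)

    def test_two_tight_clusters_cut_recovers_labels(self):
        rng = np.random.default_rng(2)
        pts = np.concatenate([rng.normal(0, 0.05, 8), rng.normal(30, 0.05, 8)])
        D, _ = euclid_matrix(pts)
        labels = hierarchical_cluster(D, linkage="ward").cut(2)
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_feature_table_input(self):
        df = pd.DataFrame(np.eye(4) * 5, index=list("abcd"))
        res = hierarchical_cluster(df, linkage="average")
        assert res.ids == ("a", "b", "c", "d")

    def test_bad_linkage_rejected(self):
        D, _ = euclid_matrix([0, 1])
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(D, linkage="centroid")


def separable_xy(seed=0, n=20):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(0, 0.3, (n, 2)), rng.normal(5, 0.3, (n, 2))])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestLMNN:
    def test_separable_classes_keep_perfect_training_accuracy(self):
        X, y = separable_xy()
        from sklearn.neighbors import KNeighborsClassifier

        model = LMNN(n_neighbors=3).fit(X, y)
        knn = KNeighborsClassifier(5)
        assert knn.fit(model.transform(X), y).score(model.transform(X), y) == 1.0

    def test_zero_iterations_is_identity_transform(self):
        X, y = separable_xy(1)
        model = LMNN(max_iter=0).fit(X, y)
        np.testing.assert_allclose(model.components_, np.eye(2))
        np.testing.assert_allclose(model.transform(X), X)

    def test_small_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="n_neighbors"):
            LMNN(n_neighbors=3).fit(X, ["A", "A", "A", "B"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            LMNN(n_neighbors=1).fit(np.zeros((4, 2)), ["A"] * 4)

    def test_silhouette_does_not_degrade_on_archetypes(self):
        rng = np.random.default_rng(0)
        X = np.concatenate(
            [rng.normal(m, 1.2, (15, 4)) for m in ((0, 0, 0, 0), (3, 0, 1, 0), (0, 3, 0, 1))]
        )
        y = np.repeat(["a", "b", "c"], 15)
        model = learn_metric(X, y, k=3)
        before = silhouette_score(X, y)
        after = silhouette_score(model.transform(X), y)
        assert after >= before - 1e-9

    def test_sklearn_params_roundtrip(self):
        model = LMNN(n_neighbors=4, margin=2.0)
        assert LMNN(**model.get_params()).get_params() == model.get_params()


class TestClassifyWithCV:
    def test_duplicated_points_perfect_and_deterministic(self):
        X = np.repeat(np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]]), 12, axis=0)
        y = np.repeat(["a", "b", "c"], 12)
        with pytest.warns(UserWarning, match="reducing folds"):
            rep = classify_with_cv(X, y, seed=0)
        assert rep.cv_mean == 1.0 and rep.cv_sd == 0.0 and rep.test_accuracy == 1.0

    def test_bitwise_reproducible_given_seed(self):
        X, y = separable_xy(3, n=18)
        X = X + np.random.default_rng(9).normal(0, 1.0, X.shape)
        a = classify_with_cv(X, y, seed=11, n_folds=4)
        b = classify_with_cv(X, y, seed=11, n_folds=4)
        assert a.cv_mean == b.cv_mean and a.cv_sd == b.cv_sd
        assert a.test_accuracy == b.test_accuracy
        np.testing.assert_array_equal(a.fold_scores, b.fold_scores)

    def test_single_class_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="single class"):
            rep = classify_with_cv(np.zeros((10, 2)), ["A"] * 10)
        assert rep.cv_mean == 1.0 and rep.test_accuracy == 1.0

    def test_dataframe_input_with_label_mapping(self):
        X, y = separable_xy(4, n=15)
        df = pd.DataFrame(X, index=[f"n{i}" for i in range(len(X))])
        rep = classify_with_cv(df, dict(zip(df.index, y)), seed=0, n_folds=5)
        assert rep.test_accuracy == 1.0


class TestStabilityProbe:
    def test_zero_jitter_zero_distance(self):
        n = generate_neuron(small_params(seed=6))
        for desc in ("branching", "wiring", "energy"):
            curve = stability_probe(n, desc, [0.0], seed=0, n_jitter=2)
            assert curve[0] == 0.0

    def test_wiring_distance_shrinks_with_jitter(self):
        n = generate_neuron(small_params(seed=8))
        eps = [0.1 * n.span_R, 0.01 * n.span_R]
        curve = stability_probe(n, "wiring", eps, seed=1, n_jitter=3)
        assert curve[1] < curve[0]

    def test_negative_epsilon_rejected(self):
        n = generate_neuron(small_params(seed=6))
        with pytest.raises(ValueError):
            stability_probe(n, "wiring", [-0.1], seed=0)
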