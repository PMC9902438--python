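"""Splitting, the from-scratch classifiers, voting, metrics, PCA and K-Means."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from cubkit.classify import (
    ConfusionMatrix,
    ModelSpec,
    compute_metrics,
    evaluate_split,
    gaussian_nb,
    hard_vote,
    kfold_cv,
    kmeans_survey,
    knn_classify,
    pca_classify,
    roc_auc,
    stratified_split,
    train_model,
)

from conftest import random_confusion_matrix


class TestStratifiedSplit:
    def test_balanced_two_class_split_is_40_10_per_class(self):
        y = np.array(["a"] * 50 + ["b"] * 50)
        train, test = stratified_split(y, test_fraction=0.2, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert (y[test] == "a").sum() == 10 and (y[train] == "a").sum() == 40
        assert not set(train) & set(test)
        assert sorted(np.concatenate([train, test])) == list(range(100))

    def test_deterministic_for_a_seed(self):
        y = np.array(["a", "b"] * 30)
        s1 = stratified_split(y, seed=7)
        s2 = stratified_split(y, seed=7)
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])
        s3 = stratified_split(y, seed=8)
        assert not np.array_equal(s1[1], s3[1])

    def test_imbalanced_proportions_preserved(self):
        y = np.array(["maj"] * 900 + ["min"] * 100)
        _, test = stratified_split(y, test_fraction=0.2, seed=1)
        assert (y[test] == "maj").sum() == 180
        assert (y[test] == "min").sum() == 20

    def test_singleton_class_is_an_error_naming_the_class(self):
        y = np.array(["a"] * 10 + ["lonely"])
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(y)


class TestKFoldCV:
    def test_separable_data_scores_one_on_every_fold(self, small_usage_table):
        table, _ = small_usage_table
        cv = kfold_cv(ModelSpec("knn", params={"k": 1}), table.X, table.kingdom, k=5, seed=0)
        assert cv.fold_accuracies == (1.0,) * 5
        assert cv.mean_accuracy == 1.0

    def test_label_shuffled_data_scores_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 8))
        y = np.array(["a", "b"] * 100)
        accs = [
            kfold_cv(ModelSpec("knn", params={"k": 5}), X, rng.permutation(y), k=5, seed=s).mean_accuracy
            for s in range(3)
        ]
        assert 0.4 < np.mean(accs) < 0.6

    def test_k_larger_than_smallest_class_rejected(self):
        X = np.zeros((6, 2))
        y = np.array(["a"] * 4 + ["b"] * 2)
        with pytest.raises(ValueError, match="smallest class"):
            kfold_cv(ModelSpec("knn"), X, y, k=3)


class TestKNN:
    def test_nearest_neighbour_toy_case(self):
        labels, votes, classes = knn_classify([[0, 0], [10, 10]], ["A", "B"], [[1, 1]], k=1)
        assert labels[0] == "A"
        assert votes[0, list(classes).index("A")] == 1.0

    def test_vote_fractions_follow_the_neighbour_share(self):
        train = [[0, 0], [0, 1], [5, 5]]
        labels, votes, classes = knn_classify(train, ["A", "A", "B"], [[0, 0.5]], k=3)
        assert labels[0] == "A"
        assert votes[0, list(classes).index("A")] == pytest.approx(2 / 3)
        assert votes[0].sum() == pytest.approx(1.0)

    def test_agrees_with_the_reference_implementation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 5))
        y = np.where(X[:, 0] + rng.normal(scale=0.3, size=120) > 0, "pos", "neg")
        Q = rng.normal(size=(40, 5))
        for k in (1, 3, 7):
            ours, _, _ = knn_classify(X, y, Q, k=k)
            ref = KNeighborsClassifier(n_neighbors=k).fit(X, y).predict(Q)
            assert (ours == ref).mean() >= 0.95  # ties may break differently

    def test_empty_training_set_and_bad_k(self):
        with pytest.raises(ValueError, match="empty"):
            knn_classify(np.empty((0, 2)), [], [[0, 0]], k=1)
        with pytest.raises(ValueError, match="k must be"):
            knn_classify([[0, 0]], ["A"], [[0, 0]], k=2)


class TestGaussianNB:
    def test_query_at_a_class_mean_is_confident(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(0, 1, (200, 1)), rng.normal(10, 1, (200, 1))]
        y = np.array(["lo"] * 200 + ["hi"] * 200)
        labels, post, classes = gaussian_nb(X, y, [[0.0], [10.0]])
        assert list(labels) == ["lo", "hi"]
        assert post.max(axis=1).min() > 0.99
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_priors_dominate_when_likelihoods_are_equal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 2))
        y = np.array(["major"] * 90 + ["minor"] * 10)
        labels, _, _ = gaussian_nb(X, y, rng.normal(0, 1, (30, 2)))
        assert (labels == "major").mean() > 0.9

    def test_constant_feature_warns_and_floors_variance(self):
        X = np.c_[np.r_[np.zeros(5), np.ones(5)], np.full(10, 3.0)]
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning, match="floored"):
            labels, _, _ = gaussian_nb(X, y, [[0.0, 3.0]])
        assert labels[0] == "a"

    def test_predictions_agree_with_the_reference_on_separated_data(self):
        rng = np.random.default_rng(2)
        X = np.r_[rng.normal(0, 1, (150, 4)), rng.normal(5, 1, (150, 4))]
        y = np.array(["a"] * 150 + ["b"] * 150)
        Q = rng.normal(2.5, 3, (60, 4))
        ours, _, _ = gaussian_nb(X, y, Q)
        ref = GaussianNB().fit(X, y).predict(Q)
        assert (ours == ref).mean() >= 0.95


class TestHardVote:
    def test_majority_tiebreak_and_identity(self):
        assert hard_vote([["A"], ["A"], ["B"]])[0] == "A"
        assert hard_vote([["A"], ["B"], ["C"]])[0] == "A"  # tie -> earliest model
        single = hard_vote([["x", "y", "z"]])
        assert list(single) == ["x", "y", "z"]

    def test_three_copies_of_one_model_equal_that_model(self):
        rng = np.random.default_rng(0)
        preds = rng.choice(["a", "b", "c"], size=50)
        assert np.array_equal(hard_vote([preds, preds, preds]), preds)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            hard_vote([["A", "B"], ["A"]])


class TestMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(("a", "b", "c"), np.diag([5, 3, 2]))
        rep = compute_metrics(cm)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.per_class_f1.values())
        assert rep.macro_f1 == rep.micro_f1 == 1.0

    def test_binary_worked_example(self):
        # TP=8, FP=2, FN=3, TN=7 for the positive class
        cm = ConfusionMatrix(("pos", "neg"), np.array([[8, 3], [2, 7]]))
        rep = compute_metrics(cm)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.per_class_precision["pos"] == pytest.approx(0.8)
        assert rep.per_class_recall["pos"] == pytest.approx(8 / 11)
        assert rep.per_class_f1["pos"] == pytest.approx(16 / 21)

    def test_micro_f1_equals_accuracy_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = random_confusion_matrix(rng)
            rep = compute_metrics(ConfusionMatrix(tuple(range(len(m))), m))
            assert rep.micro_f1 == pytest.approx(rep.accuracy, abs=1e-12)

    def test_macro_f1_is_the_harmonic_mean_of_macro_precision_and_recall(self):
        # the macro-F1 definition used here harmonically combines the
        # macro-averaged precision and recall; note it is NOT the mean of
        # per-class F1s and can lie outside their range
        rng = np.random.default_rng(6)
        for _ in range(100):
            m = random_confusion_matrix(rng)
            with np.errstate(all="ignore"):
                rep = compute_metrics(ConfusionMatrix(tuple(range(len(m))), m))
            if rep.macro_precision + rep.macro_recall > 0:
                expected = (2 * rep.macro_precision * rep.macro_recall
                            / (rep.macro_precision + rep.macro_recall))
                assert rep.macro_f1 == pytest.approx(expected, abs=1e-12)
            assert rep.macro_precision == pytest.approx(
                np.mean(list(rep.per_class_precision.values())), abs=1e-12
            )

    def test_matches_brute_force_per_sample_tally(self):
        rng = np.random.default_rng(7)
        labels = ("x", "y", "z")
        y_true = rng.choice(labels, size=200)
        y_pred = rng.choice(labels, size=200)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, labels=labels)
        rep = compute_metrics(cm)
        for lab in labels:
            tp = np.sum((y_true == lab) & (y_pred == lab))
            fp = np.sum((y_true != lab) & (y_pred == lab))
            fn = np.sum((y_true == lab) & (y_pred != lab))
            assert cm.one_vs_rest(lab)[:3] == (tp, fp, fn)
        p, r, f, _ = precision_recall_fscore_support(y_true, y_pred, labels=labels, zero_division=0)
        np.testing.assert_allclose([rep.per_class_precision[l] for l in labels], p, atol=1e-12)
        np.testing.assert_allclose([rep.per_class_recall[l] for l in labels], r, atol=1e-12)
        np.testing.assert_allclose([rep.per_class_f1[l] for l in labels], f, atol=1e-12)

    def test_zero_denominator_reports_zero_with_warning(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[5, 0], [3, 0]]))  # nothing predicted b
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = compute_metrics(cm)
        assert rep.per_class_precision["b"] == 0.0


class TestRocAuc:
    def test_perfect_and_chance_scores(self):
        y = np.array(["p", "p", "n", "n"])
        perfect = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.7, 0.3]])
        assert roc_auc(perfect, y, classes=["n", "p"]) == pytest.approx(1.0)
        constant = np.full((4, 2), 0.5)
        assert roc_auc(constant, y, classes=["n", "p"]) == pytest.approx(0.5)

    def test_worked_interleaved_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        y = np.array(["+", "-", "+", "-"])
        auc = roc_auc(np.c_[1 - scores, scores], y, classes=["-", "+"])
        assert auc == pytest.approx(0.75)  # 3 of 4 (positive, negative) pairs ordered

    def test_equals_the_mann_whitney_pairwise_statistic(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(8, 40))
            scores = rng.normal(size=n)  # continuous: ties have measure zero
            y = rng.choice(["pos", "neg"], size=n)
            if len(set(y)) < 2:
                continue
            auc = roc_auc(np.c_[-scores, scores], y, classes=["neg", "pos"])
            pos, neg = scores[y == "pos"], scores[y == "neg"]
            pairwise = np.mean([p > q for p in pos for q in neg])
            assert auc == pytest.approx(pairwise, abs=1e-12)
            assert auc == pytest.approx(roc_auc_score((y == "pos").astype(int), scores), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            roc_auc(np.ones((3, 2)), ["a", "a", "a"], classes=["a", "b"])


class TestTrainModel:
    def test_knn_k1_memorizes_distinct_training_points(self, small_usage_table):
        table, _ = small_usage_table
        model = train_model(ModelSpec("knn", params={"k": 1}), table.X, table.kingdom)
        assert (model.predict(table.X) == table.kingdom).all()

    def test_identical_spec_and_seed_reproduce_predictions(self, small_usage_table):
        table, _ = small_usage_table
        spec = ModelSpec("rf", params={"n_estimators": 50}, seed=3)
        m1 = train_model(spec, table.X, table.kingdom)
        m2 = train_model(spec, table.X, table.kingdom)
        assert np.array_equal(m1.predict(table.X), m2.predict(table.X))

    @pytest.mark.parametrize("kind", ["svm", "rf", "xgb", "gnb", "ensemble"])
    def test_wrapped_models_fit_separable_data(self, small_usage_table, kind):
        table, _ = small_usage_table
        params = {"n_estimators": 60} if kind in ("rf", "xgb") else {}
        spec = ModelSpec(kind, params=params, preset="kingdom", seed=0)
        rep = evaluate_split(spec, table.X, table.kingdom, seed=0)
        assert rep.accuracy >= 0.9

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            train_model(ModelSpec("zoo"), np.zeros((4, 2)), ["a", "a", "b", "b"])


class TestPcaClassify:
    def test_full_rank_projection_preserves_knn_metrics(self, small_usage_table):
        table, _ = small_usage_table
        full = evaluate_split(ModelSpec("knn", params={"k": 3}), table.X, table.kingdom, seed=2)
        reduced = pca_classify(table.X, table.kingdom, n_components=64, knn_k=3, seed=2)
        assert reduced.accuracy == pytest.approx(full.accuracy)

    def test_separable_classes_survive_heavy_reduction(self, small_usage_table):
        table, _ = small_usage_table
        rep = pca_classify(table.X, table.kingdom, n_components=2, knn_k=3, seed=0)
        assert rep.accuracy >= 0.9

    def test_isotropic_noise_gives_chance_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 64))
        y = np.array(["a", "b"] * 200)
        rep = pca_classify(X, y, n_components=1, knn_k=3, seed=0)
        assert 0.35 <= rep.accuracy <= 0.65

    def test_too_many_components_rejected(self, small_usage_table):
        table, _ = small_usage_table
        with pytest.raises(ValueError, match="n_components"):
            pca_classify(table.X, table.kingdom, n_components=65)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0], [12, 0], [0, 12]])
    return np.concatenate([rng.normal(c, 0.5, size=(60, 2)) for c in centers])


class TestKMeansSurvey:
    def test_silhouette_peaks_at_the_true_cluster_count(self, blobs):
        survey = kmeans_survey(blobs, range(2, 7), seed=0)
        assert survey.best_k_by_silhouette() == 3

    def test_inertia_non_increasing_in_k(self, blobs):
        survey = kmeans_survey(blobs, range(2, 8), seed=0)
        assert all(a >= b - 1e-9 for a, b in zip(survey.inertia, survey.inertia[1:]))

    def test_k_below_two_rejected(self, blobs):
        with pytest.raises(ValueError, match="out of range"):
            kmeans_survey(blobs, [1, 2], seed=0)
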