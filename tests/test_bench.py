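"""Stratified splitting, nested grid search, metrics, ROC, diagnostics."""

import numpy as np
import pytest

import sarcospec as ss
from sarcospec.bench import FoldRecord, LearningCurvePoint, decision_scores


class FixedPredictor:
    """Stub classifier returning canned labels and scores."""

    def __init__(self, labels, scores):
        self.labels = np.asarray(labels)
        self.scores = np.asarray(scores, dtype=float)
        self.classes_ = np.array(["healthy", "sarcoma"])

    def predict(self, X):
        return self.labels

    def predict_proba(self, X):
        p = self.scores
        return np.column_stack([1 - p, p])


def two_cluster_data(n_per_class=40, n_features=5, gap=6.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, noise, size=(n_per_class, n_features))
    b = rng.normal(gap, noise, size=(n_per_class, n_features))
    X = np.vstack([a, b])
    y = np.array(["healthy"] * n_per_class + ["sarcoma"] * n_per_class)
    return X, y


class TestStratifiedSplit:
    def test_study_counts_round_half_up_per_class(self):
        y = np.array(["sarcoma"] * 393 + ["healthy"] * 118)
        train, test = ss.stratified_split(y, ss.CVPlan(seed=0))
        assert (y[test] == "sarcoma").sum() == 79
        assert (y[test] == "healthy").sum() == 24
        assert len(test) == 103 and len(train) == 408
        assert np.intersect1d(train, test).size == 0

    def test_balanced_ten_sample_set(self):
        y = np.array(["sarcoma", "healthy"] * 5)
        plan = ss.CVPlan(seed=1, outer_folds=2)
        train, test = ss.stratified_split(y, plan)
        assert len(train) == 8 and len(test) == 2
        assert sorted(y[test]) == ["healthy", "sarcoma"]

    def test_same_seed_gives_identical_indices(self):
        y = np.array(["sarcoma"] * 40 + ["healthy"] * 20)
        a = ss.stratified_split(y, ss.CVPlan(seed=5))
        b = ss.stratified_split(y, ss.CVPlan(seed=5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_group_mode_keeps_groups_intact(self):
        y = np.array(["sarcoma"] * 30 + ["healthy"] * 30)
        groups = np.array([f"m{i // 10}" for i in range(60)])
        train, test = ss.stratified_split(y, ss.CVPlan(seed=2), groups=groups)
        assert set(groups[train]).isdisjoint(set(groups[test]))

    def test_class_smaller_than_folds_errors(self):
        y = np.array(["sarcoma"] * 10 + ["healthy"] * 3)
        with pytest.raises(ValueError):
            ss.stratified_split(y, ss.CVPlan(seed=0))


class TestNestedGridSearch:
    def test_single_combination_grid_is_returned(self):
        X, y = two_cluster_data(seed=3)
        grid = ss.HyperparameterGrid("knn", {"n_neighbors": [5]})
        result = ss.nested_grid_search(X, y, "knn", grid, ss.CVPlan(seed=3), use_pca=False)
        assert result.best_params == {"n_neighbors": 5}
        assert all(r.best_params == {"n_neighbors": 5} for r in result.fold_records)

    def test_outer_fold_sizes_partition_408_rows(self):
        y = np.array(["sarcoma"] * 316 + ["healthy"] * 92)  # 408 training rows
        rng = np.random.default_rng(4)
        X = rng.normal(size=(408, 3))
        grid = ss.HyperparameterGrid("knn", {"n_neighbors": [5]})
        result = ss.nested_grid_search(X, y, "knn", grid, ss.CVPlan(seed=4), use_pca=False)
        sizes = sorted(len(r.val_indices) for r in result.fold_records)
        assert sizes == [81, 81, 82, 82, 82]
        all_val = np.concatenate([r.val_indices for r in result.fold_records])
        assert sorted(all_val.tolist()) == list(range(408))

    def test_small_k_wins_on_two_cluster_data(self):
        # k larger than the minority class drowns it in majority votes, so
        # the small k dominates on clearly separated clusters
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (25, 5)), rng.normal(8, 1, (75, 5))])
        y = np.array(["healthy"] * 25 + ["sarcoma"] * 75)
        grid = ss.HyperparameterGrid("knn", {"n_neighbors": [1, 45], "weights": ["uniform"]})
        result = ss.nested_grid_search(X, y, "knn", grid, ss.CVPlan(seed=5), use_pca=False)
        assert result.best_params["n_neighbors"] == 1
        for record in result.fold_records:
            assert record.best_params["n_neighbors"] == 1

    def test_invalid_logistic_cells_are_skipped_not_fatal(self):
        X, y = two_cluster_data(seed=6)
        grid = ss.HyperparameterGrid(
            "logistic", {"C": [1.0], "solver": ["newton-cg"], "penalty": ["l1", "l2"]}
        )
        result = ss.nested_grid_search(X, y, "logistic", grid, ss.CVPlan(seed=6), use_pca=False)
        assert result.best_params["penalty"] == "l2"
        assert {"C": 1.0, "solver": "newton-cg", "penalty": "l1"} in result.skipped_combinations

    def test_no_leakage_between_folds_and_grid_membership(self):
        X, y = two_cluster_data(n_per_class=35, gap=3.0, seed=7)
        grid = ss.default_grid("knn")
        result = ss.nested_grid_search(X, y, "knn", grid, ss.CVPlan(seed=7), use_pca=False)
        combos = grid.combinations()
        assert result.best_params in combos
        for record in result.fold_records:
            assert record.best_params in combos
            assert np.intersect1d(record.train_indices, record.val_indices).size == 0
            assert len(record.train_indices) + len(record.val_indices) == len(y)


class TestEvaluate:
    def test_perfect_predictions_score_one_everywhere(self):
        y = np.array(["sarcoma"] * 6 + ["healthy"] * 2)
        model = FixedPredictor(y, np.where(y == "sarcoma", 0.9, 0.1))
        m = ss.evaluate_classifier(model, np.zeros((8, 1)), y)
        for name in ("accuracy", "specificity", "precision_pos", "precision_macro",
                     "recall_pos", "recall_macro", "f1_pos", "f1_macro", "auc"):
            assert getattr(m, name) == pytest.approx(1.0), name

    def test_degenerate_all_sarcoma_predictor_on_imbalanced_test(self):
        y = np.array(["sarcoma"] * 9 + ["healthy"] * 3)
        model = FixedPredictor(np.array(["sarcoma"] * 12), np.full(12, 0.5))
        m = ss.evaluate_classifier(model, np.zeros((12, 1)), y)
        assert m.accuracy == pytest.approx(0.75)
        assert m.specificity == 0.0
        assert m.recall_pos == 1.0
        assert m.auc == pytest.approx(0.5)

    def test_hand_computed_confusion_matrix_metrics(self):
        # TP=90, FN=9, TN=18, FP=6
        y = np.array(["sarcoma"] * 99 + ["healthy"] * 24)
        pred = np.array(["sarcoma"] * 90 + ["healthy"] * 9 + ["healthy"] * 18 + ["sarcoma"] * 6)
        scores = np.where(pred == "sarcoma", 0.9, 0.1)
        m = ss.evaluate_classifier(FixedPredictor(pred, scores), np.zeros((123, 1)), y)
        assert (m.tp, m.fn, m.tn, m.fp) == (90, 9, 18, 6)
        assert m.accuracy == pytest.approx(108 / 123)
        assert m.specificity == pytest.approx(18 / 24)
        precision_pos, recall_pos = 90 / 96, 90 / 99
        precision_neg, recall_neg = 18 / 27, 18 / 24
        f1 = lambda p, r: 2 * p * r / (p + r)
        assert m.precision_macro == pytest.approx((precision_pos + precision_neg) / 2)
        assert m.recall_macro == pytest.approx((recall_pos + recall_neg) / 2)
        assert m.f1_pos == pytest.approx(f1(precision_pos, recall_pos))
        assert m.f1_macro == pytest.approx((f1(precision_pos, recall_pos) + f1(precision_neg, recall_neg)) / 2)

    def test_single_class_test_set_errors(self):
        y = np.array(["sarcoma"] * 5)
        model = FixedPredictor(y, np.full(5, 0.9))
        with pytest.raises(ValueError):
            ss.evaluate_classifier(model, np.zeros((5, 1)), y)


class TestROC:
    def test_perfectly_separated_scores_give_auc_one(self):
        labels = np.array(["healthy"] * 4 + ["sarcoma"] * 4)
        *_, auc = ss.roc_with_auc([0, 1, 2, 3, 10, 11, 12, 13], labels)
        assert auc == 1.0

    def test_constant_scores_give_auc_half(self):
        labels = np.array(["healthy"] * 4 + ["sarcoma"] * 4)
        *_, auc = ss.roc_with_auc(np.zeros(8), labels)
        assert auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_u_over_pair_count(self):
        """Rank-statistic identity, cross-checked against the in-repo U."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            n1, n2 = rng.integers(3, 15, size=2)
            scores = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n2)])
            labels = np.array(["sarcoma"] * n1 + ["healthy"] * n2)
            *_, auc = ss.roc_with_auc(scores, labels)
            u, _ = ss.mann_whitney_u(scores[:n1], scores[n1:])
            assert auc == pytest.approx(u / (n1 * n2))

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            ss.roc_with_auc([1, 2, 3], np.array(["sarcoma"] * 3))


class TestLearningCurve:
    def test_nine_fractions_give_nine_points(self, small_labeled_dataset):
        X = small_labeled_dataset.intensity_matrix()
        y = small_labeled_dataset.labels()
        points = ss.learning_curve(X, y, "logistic", {"C": 1.0, "solver": "lbfgs"},
                                   plan=ss.CVPlan(seed=13))
        assert len(points) == 9
        assert all(isinstance(p, LearningCurvePoint) for p in points)
        assert [p.fraction for p in points] == pytest.approx(np.arange(0.1, 1.0, 0.1).tolist())

    def test_separable_data_validates_perfectly(self):
        X, y = two_cluster_data(n_per_class=50, gap=10.0, noise=0.5, seed=14)
        points = ss.learning_curve(X, y, "knn", {"n_neighbors": 5},
                                   fractions=(0.3, 0.6, 0.9), plan=ss.CVPlan(seed=14),
                                   use_pca=False)
        assert all(p.val_mean == pytest.approx(1.0) for p in points)

    def test_overfit_prone_model_trains_above_validation(self):
        X, y = two_cluster_data(n_per_class=60, gap=1.0, noise=2.0, seed=15)
        points = ss.learning_curve(X, y, "knn", {"n_neighbors": 1},
                                   fractions=(0.2, 0.5, 0.8), plan=ss.CVPlan(seed=15),
                                   use_pca=False)
        assert all(p.train_mean >= p.val_mean for p in points)

    def test_fractions_outside_unit_interval_error(self):
        with pytest.raises(ValueError):
            ss.learning_curve(np.zeros((10, 2)), np.array(["sarcoma"] * 5 + ["healthy"] * 5),
                              "knn", fractions=(0.0, 0.5))


class TestSampleSize:
    def test_closed_form_inversion(self):
        """acc(n) = 0.95 - 2 n^-0.5 hits 0.90 at n = (2 / 0.05)^2 = 1600."""
        ns = [25, 50, 100, 200]
        points = [(n, 0.95 - 2.0 * n**-0.5) for n in ns]
        estimate = ss.estimate_sample_size(points, target_accuracy=0.90)
        assert estimate.attainable
        assert estimate.n_required == 1600
        assert (estimate.a, estimate.b, estimate.c) == pytest.approx((0.95, 2.0, 0.5), rel=1e-4)

    def test_target_above_asymptote_is_flagged(self):
        points = [(n, 0.85 - 1.0 * n**-0.5) for n in (25, 50, 100, 200, 400)]
        estimate = ss.estimate_sample_size(points, target_accuracy=0.95)
        assert not estimate.attainable
        assert estimate.n_required is None

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            ss.estimate_sample_size([(10, 0.5), (20, 0.6), (30, 0.7)])


class TestPipelineScores:
    def test_decision_scores_orient_toward_sarcoma(self):
        X, y = two_cluster_data(n_per_class=20, gap=5.0, seed=16)
        model = ss.make_estimator("logistic", {"C": 1.0, "solver": "lbfgs"}, use_pca=False)
        model.fit(X, y)
        scores = decision_scores(model, X)
        assert scores[y == "sarcoma"].mean() > scores[y == "healthy"].mean()
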