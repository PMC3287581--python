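"""Metric arithmetic, cross-validation behavior, tuning, delta reporting."""

import numpy as np
import pytest

from csmkit import (
    ClassifierSpec,
    build_csm_matrix,
    compare_runs,
    compute_metrics,
    cross_validate,
    decompose,
    format_delta,
    make_preset_dataset,
    project,
    select_level,
    tune_hyperparameters,
)
from csmkit.datasets import LabeledDataset
from csmkit.errors import ComparisonError, StratificationError


class _ArrayFeatures:
    """Minimal feature container for hand-built datasets."""

    def __init__(self, values, row_ids=None):
        self.values = np.asarray(values, dtype=float)
        self.row_ids = row_ids or [f"r{i}" for i in range(len(self.values))]

    def take(self, idx):
        idx = list(idx)
        return _ArrayFeatures(self.values[idx], [self.row_ids[i] for i in idx])


def make_dataset(X, y):
    return LabeledDataset(_ArrayFeatures(X), np.asarray(y, dtype=object), "family")


class TestComputeMetrics:
    def test_binary_confusion_direct_formulas(self):
        report = compute_metrics(np.array([[9, 1], [1, 9]]), ["pos", "neg"])
        for cls in ("pos", "neg"):
            m = report.per_class[cls]
            assert m["precision"] == pytest.approx(0.9)
            assert m["recall"] == pytest.approx(0.9)
            assert m["f1"] == pytest.approx(0.9)

    def test_perfect_diagonal_gives_all_ones(self):
        report = compute_metrics(np.diag([4, 6, 2]), ["a", "b", "c"])
        assert report.weighted_avg["precision"] == pytest.approx(1.0)
        assert report.weighted_avg["recall"] == pytest.approx(1.0)
        assert report.weighted_avg["f1"] == pytest.approx(1.0)

    def test_three_class_hand_computation(self):
        C = np.array([[5, 0, 0], [1, 4, 0], [0, 2, 3]])
        report = compute_metrics(C, ["c1", "c2", "c3"])
        assert report.per_class["c1"]["precision"] == pytest.approx(5 / 6)
        assert report.weighted_avg["recall"] == pytest.approx((5 + 4 + 3) / 15)

    def test_weighted_averages_are_support_weighted_means(self):
        rng = np.random.default_rng(0)
        C = rng.integers(0, 20, size=(4, 4))
        classes = list("abcd")
        report = compute_metrics(C, classes)
        support = C.sum(axis=1)
        for key in ("precision", "recall", "f1"):
            manual = sum(
                report.per_class[c][key] * s for c, s in zip(classes, support)
            ) / support.sum()
            assert report.weighted_avg[key] == pytest.approx(manual, abs=1e-12)

    def test_micro_precision_recall_accuracy_coincide(self):
        rng = np.random.default_rng(1)
        C = rng.integers(0, 15, size=(3, 3))
        tp = np.diag(C).sum()
        micro_precision = tp / C.sum(axis=0).sum()
        micro_recall = tp / C.sum(axis=1).sum()
        accuracy = compute_metrics(C, list("abc")).accuracy
        assert micro_precision == pytest.approx(micro_recall) == pytest.approx(accuracy)

    def test_never_predicted_class_flagged_with_zero_precision(self):
        C = np.array([[3, 0], [2, 0]])  # class 'b' never predicted
        report = compute_metrics(C, ["a", "b"])
        assert report.per_class["b"]["precision"] == 0.0
        assert report.undefined_precision == ["b"]

    def test_non_square_matrix_rejected(self):
        with pytest.raises(ValueError, match="square"):
            compute_metrics(np.ones((2, 3)), ["a", "b"])

    def test_auc_from_scores_is_one_vs_rest(self):
        y = np.array(["a", "a", "b", "b"])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.4, 0.6]])
        C = np.array([[2, 0], [0, 2]])
        report = compute_metrics(C, ["a", "b"], y_true=y, scores=scores)
        assert report.per_class["a"]["auc"] == 1.0
        assert report.weighted_avg["auc"] == 1.0


class TestCrossValidate:
    def test_separable_synthetic_classes_classified_perfectly(self):
        chains, table = make_preset_dataset("two-class", n_per_class=20,
                                            noise_sd=0.1, length=40, seed=3)
        features = build_csm_matrix(chains)
        ds = select_level(table, features, "family")
        report = cross_validate(ds, ClassifierSpec("knn", {"k_nn": 3}), folds=10, seed=3)
        assert report.weighted_avg["precision"] == 1.0
        assert report.weighted_avg["recall"] == 1.0

    def test_coin_flip_labels_on_identical_rows_score_near_chance(self):
        rng = np.random.default_rng(12)
        X = np.ones((200, 5))
        y = np.where(rng.random(200) < 0.5, "h", "t")
        # guard the draw: both classes must support 10 folds
        assert min((y == "h").sum(), (y == "t").sum()) >= 10
        report = cross_validate(make_dataset(X, y), ClassifierSpec("knn", {"k_nn": 5}),
                                folds=10, seed=12)
        assert 0.4 <= report.weighted_avg["precision"] <= 0.6

    def test_every_row_predicted_exactly_once(self):
        chains, table = make_preset_dataset("two-class", n_per_class=15, seed=5)
        ds = select_level(table, build_csm_matrix(chains), "family")
        report = cross_validate(ds, ClassifierSpec("knn"), folds=5, seed=5)
        assert report.confusion.sum() == len(ds)

    def test_class_smaller_than_folds_raises_naming_it(self):
        X = np.vstack([np.zeros((12, 3)), np.ones((4, 3))])
        y = ["big"] * 12 + ["tiny"] * 4
        with pytest.raises(StratificationError, match="tiny"):
            cross_validate(make_dataset(X, y), ClassifierSpec("knn"), folds=10)

    def test_same_seed_gives_identical_report(self):
        chains, table = make_preset_dataset("two-class", n_per_class=15,
                                            noise_sd=1.5, seed=8)
        ds = select_level(table, build_csm_matrix(chains), "family")
        spec = ClassifierSpec("random_forest", {"n_trees": 20}, seed=8)
        a = cross_validate(ds, spec, folds=5, seed=8)
        b = cross_validate(ds, spec, folds=5, seed=8)
        assert np.array_equal(a.confusion, b.confusion)
        assert a.weighted_avg == b.weighted_avg

    @pytest.mark.parametrize("algorithm,hp", [
        ("naive_bayes", {}),
        ("random_forest", {"n_trees": 25}),
    ])
    def test_other_algorithms_separate_easy_classes(self, algorithm, hp):
        chains, table = make_preset_dataset("two-class", n_per_class=12,
                                            noise_sd=0.1, seed=4)
        ds = select_level(table, build_csm_matrix(chains), "family")
        report = cross_validate(ds, ClassifierSpec(algorithm, hp, seed=4), folds=4)
        assert report.weighted_avg["precision"] >= 0.9

    def test_knn_at_full_svd_rank_equals_raw_knn(self):
        chains, table = make_preset_dataset("two-class", n_per_class=12,
                                            noise_sd=1.0, seed=9)
        features = build_csm_matrix(chains)
        ds_raw = select_level(table, features, "family")
        model = decompose(ds_raw.features)
        ds_proj = ds_raw.with_features(project(model, model.p))
        spec = ClassifierSpec("knn", {"k_nn": 3})
        a = cross_validate(ds_raw, spec, folds=4, seed=9)
        b = cross_validate(ds_proj, spec, folds=4, seed=9)
        assert np.array_equal(a.confusion, b.confusion)


class TestTuneHyperparameters:
    def test_ties_broken_by_grid_order(self):
        chains, table = make_preset_dataset("two-class", n_per_class=12,
                                            noise_sd=0.05, seed=6)
        ds = select_level(table, build_csm_matrix(chains), "family")
        grid = [ClassifierSpec("knn", {"k_nn": k}) for k in (1, 3, 5)]
        best, report = tune_hyperparameters(ds, grid, folds=4, seed=6)
        assert report.weighted_avg["precision"] == 1.0
        assert best.hyperparameters["k_nn"] == 1

    def test_single_spec_grid_equals_cross_validate(self):
        chains, table = make_preset_dataset("two-class", n_per_class=12, seed=7)
        ds = select_level(table, build_csm_matrix(chains), "family")
        spec = ClassifierSpec("knn", {"k_nn": 3})
        best, report = tune_hyperparameters(ds, [spec], folds=4, seed=7)
        direct = cross_validate(ds, spec, folds=4, seed=7)
        assert best is spec
        assert np.array_equal(report.confusion, direct.confusion)

    def test_selects_max_precision_verified_by_exhaustive_evaluation(self):
        chains, table = make_preset_dataset("two-class", n_per_class=15,
                                            noise_sd=3.0, seed=10)
        ds = select_level(table, build_csm_matrix(chains), "family")
        grid = [ClassifierSpec("knn", {"k_nn": k}) for k in (1, 3, 5, 7)]
        best, report = tune_hyperparameters(ds, grid, folds=5, seed=10)
        scores = [
            cross_validate(ds, spec, folds=5, seed=10).weighted_avg["precision"]
            for spec in grid
        ]
        assert report.weighted_avg["precision"] == max(scores)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(make_dataset(np.ones((4, 2)), list("aabb")), [])


class TestCompareRuns:
    def test_delta_formatting_is_percentage_points(self):
        assert format_delta(0.901, 0.991) == "+9.0%"
        assert format_delta(0.903, 0.989) == "+8.6%"
        assert format_delta(0.5, 0.5) == "+0.0%"
        assert format_delta(0.95, 0.90) == "-5.0%"

    def test_identical_reports_have_zero_deltas(self):
        report = compute_metrics(np.diag([5, 5]), ["a", "b"])
        table = compare_runs(report, report)
        assert table["weighted avg"]["delta_precision"] == "+0.0%"
        assert table["a"]["delta_recall"] == "+0.0%"

    def test_mismatched_class_sets_rejected(self):
        a = compute_metrics(np.diag([5, 5]), ["a", "b"])
        b = compute_metrics(np.diag([5, 5]), ["a", "c"])
        with pytest.raises(ComparisonError):
            compare_runs(a, b)

    def test_per_class_deltas_from_reports(self):
        before = compute_metrics(np.array([[8, 2], [1, 9]]), ["a", "b"])
        after = compute_metrics(np.array([[10, 0], [0, 10]]), ["a", "b"])
        table = compare_runs(before, after)
        expected = format_delta(before.per_class["a"]["precision"], 1.0)
        assert table["a"]["delta_precision"] == expected


class TestClassifierSpec:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm")

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("knn", {"n_trees": 5})
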