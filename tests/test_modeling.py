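"""Metrics, regressors, cross-validation and class mapping."""

import numpy as np
import pytest

from eegaffect import (
    AffectPrediction,
    EEGAffectError,
    FeatureMatrix,
    MetricUndefinedError,
    RegressorSpec,
    binary_accuracy,
    cross_validate,
    fit_predict_knn,
    fit_predict_rf,
    make_folds,
    metrics,
    quadrant_confusion,
    to_binary,
    to_quadrant,
)


def brute_force_metrics(y, yhat):
    """Straight transcriptions of the three accuracy formulas."""
    n = len(y)
    mae = sum(abs(yhat[i] - y[i]) for i in range(n)) / n
    rmse = (sum((yhat[i] - y[i]) ** 2 for i in range(n)) / n) ** 0.5
    num = n * sum(yhat[i] * y[i] for i in range(n)) - sum(yhat) * sum(y)
    den = (
        (n * sum(v ** 2 for v in yhat) - sum(yhat) ** 2) ** 0.5
        * (n * sum(v ** 2 for v in y) - sum(y) ** 2) ** 0.5
    )
    return mae, rmse, num / den


def random_matrix(n=40, d=5, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    targets = labels if labels is not None else rng.uniform(0, 1, size=(n, 2))
    return FeatureMatrix(
        X=X,
        schema=[{"kind": "channel", "wave": "beta", "channel": f"c{j}", "feature": "H1"}
                for j in range(d)],
        targets=np.asarray(targets, dtype=float),
        subject_ids=[f"s{i % 4}" for i in range(n)],
        trial_ids=[f"t{i}" for i in range(n)],
        epoch_indices=list(range(n)),
    )


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.4, 0.9])
        assert metrics(y, y) == pytest.approx((0.0, 0.0, 1.0))

    def test_anti_perfect_prediction(self):
        mae, rmse, pcc = metrics([0.0, 1.0], [1.0, 0.0])
        assert (mae, rmse, pcc) == pytest.approx((1.0, 1.0, -1.0))

    def test_worked_example(self):
        mae, rmse, pcc = metrics([0.0, 0.5, 1.0], [0.1, 0.5, 0.9])
        assert mae == pytest.approx(0.0667, abs=1e-3)
        assert rmse == pytest.approx(0.0816, abs=1e-3)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.uniform(0, 1, size=20)
            yhat = rng.uniform(0, 1, size=20)
            got = metrics(y, yhat)
            expected = brute_force_metrics(list(y), list(yhat))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_pcc_is_an_error_not_zero(self):
        with pytest.raises(MetricUndefinedError):
            metrics([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


class TestKnn:
    def test_query_equal_to_training_row_returns_its_labels(self):
        X = np.array([[0.0, 0.0], [3.0, 1.0], [5.0, 5.0]])
        y = np.array([0.1, 0.5, 0.9])
        assert fit_predict_knn(X, y, X[1:2], k=1)[0] == 0.5

    def test_equidistant_tie_broken_by_lowest_index(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([0.2, 0.8])
        assert fit_predict_knn(X, y, [[0.0]], k=1)[0] == 0.2

    def test_k_equal_n_returns_global_mean(self):
        X = np.arange(6.0).reshape(-1, 1)
        y = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        assert fit_predict_knn(X, y, [[2.5]], k=6)[0] == pytest.approx(y.mean())

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(EEGAffectError):
            fit_predict_knn(np.zeros((3, 2)), np.zeros(3), np.zeros((1, 2)), k=4)

    def test_equals_exhaustive_nearest_neighbour_search(self):
        rng = np.random.default_rng(5)
        train = rng.standard_normal((30, 4))
        y = rng.uniform(0, 1, 30)
        queries = rng.standard_normal((10, 4))
        got = fit_predict_knn(train, y, queries, k=1)
        for qi, q in enumerate(queries):
            dists = [np.sum(np.abs(q - row)) for row in train]
            assert got[qi] == y[int(np.argmin(dists))]

    def test_agrees_with_sklearn_on_manhattan_neighbours(self):
        from sklearn.neighbors import KNeighborsRegressor

        rng = np.random.default_rng(6)
        train = rng.standard_normal((50, 8))
        y = rng.uniform(0, 1, 50)
        queries = rng.standard_normal((20, 8))
        ours = fit_predict_knn(train, y, queries, k=3)
        theirs = (
            KNeighborsRegressor(n_neighbors=3, metric="manhattan")
            .fit(train, y)
            .predict(queries)
        )
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestRandomForest:
    def test_constant_labels_give_constant_prediction(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = np.full(20, 0.7)
        pred = fit_predict_rf(X, y, X[:5], n_trees=20, seed=1)
        np.testing.assert_allclose(pred, 0.7)

    def test_same_seed_is_bitwise_identical(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = rng.uniform(0, 1, 30)
        q = rng.standard_normal((8, 4))
        a = fit_predict_rf(X, y, q, n_trees=30, seed=7)
        b = fit_predict_rf(X, y, q, n_trees=30, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_predictions_bounded_by_training_labels(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = rng.uniform(0.3, 0.6, 30)
        pred = fit_predict_rf(X, y, rng.standard_normal((10, 4)), n_trees=30, seed=0)
        assert np.all(pred >= y.min()) and np.all(pred <= y.max())


class TestFolds:
    def test_partition_properties(self):
        folds = make_folds(43, 10, seed=3)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(43))

    def test_grouped_folds_keep_groups_intact(self):
        groups = [f"s{i // 5}" for i in range(40)]  # 8 subjects, 5 rows each
        folds = make_folds(40, 4, seed=0, groups=groups)
        for fold in folds:
            fold_groups = {groups[i] for i in fold}
            for g in fold_groups:
                members = [i for i in range(40) if groups[i] == g]
                assert set(members) <= set(fold.tolist())

    def test_too_many_folds_rejected(self):
        with pytest.raises(EEGAffectError):
            make_folds(5, 10, seed=0)


class TestCrossValidation:
    def test_memorisation_bound_with_knn_on_train_rows(self):
        m = random_matrix(n=30, seed=8)
        pred = fit_predict_knn(m.X, m.targets[:, 0], m.X, k=1)
        assert metrics(m.targets[:, 0], pred)[0] == pytest.approx(0.0, abs=1e-12)

    def test_report_structure_and_quadrant_trace(self):
        m = random_matrix(n=40, seed=9)
        report = cross_validate(m, RegressorSpec(kind="knn"), n_folds=5, seed=1)
        assert len(report.per_fold) == 5
        agg = report.aggregate()
        assert set(agg) == {"valence", "arousal"}
        cm = report.quadrant_confusion_matrix
        assert cm.sum() == m.n_rows
        assert report.quadrant_accuracy == pytest.approx(
            100.0 * np.trace(cm) / cm.sum()
        )

    def test_deterministic_given_seed(self):
        m = random_matrix(n=40, seed=10)
        spec = RegressorSpec(kind="rf", n_trees=20, seed=4)
        r1 = cross_validate(m, spec, n_folds=4, seed=2)
        r2 = cross_validate(m, spec, n_folds=4, seed=2)
        assert r1.per_fold == r2.per_fold

    def test_grouped_mode_separates_subject_epochs(self):
        m = random_matrix(n=40, seed=11)
        report = cross_validate(
            m, RegressorSpec(kind="knn"), n_folds=4, seed=0, group_by_subject=True
        )
        assert len(report.per_fold) == 4

    @pytest.mark.parametrize(
        "kind", ["linear", "decision_tree", "additive", "svr_linear", "svr_rbf"]
    )
    def test_baseline_regressors_run(self, kind):
        m = random_matrix(n=30, seed=12)
        report = cross_validate(m, RegressorSpec(kind=kind, seed=0), n_folds=3, seed=0)
        for fold in report.per_fold:
            for target in ("valence", "arousal"):
                mae, rmse, _ = fold[target]
                assert np.isfinite(mae) and np.isfinite(rmse)


class TestClassMapping:
    @pytest.mark.parametrize(
        "valence,arousal,quadrant",
        [
            (0.8, 0.8, "HAHV"),
            (0.2, 0.8, "HALV"),
            (0.2, 0.2, "LALV"),
            (0.8, 0.2, "LAHV"),
            (0.5, 0.5, "HAHV"),  # threshold inclusive on both axes
        ],
    )
    def test_quadrant_mapping(self, valence, arousal, quadrant):
        assert to_quadrant(AffectPrediction(valence, arousal)) == quadrant

    def test_binary_mapping_threshold_inclusive(self):
        assert to_binary(AffectPrediction(0.5, 0.49)) == ("high", "low")

    def test_binary_accuracy_examples(self):
        assert binary_accuracy(["L", "H"], ["L", "H"]) == 100.0
        assert binary_accuracy(["L", "L", "H", "H"], ["H", "H", "H", "H"]) == 50.0
        assert binary_accuracy(["L", "L", "H", "H"], ["L", "H", "H", "H"]) == 75.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(EEGAffectError):
            binary_accuracy(["H", "H"], ["H", "L"])

    def test_confusion_rows_sum_to_true_counts(self):
        truth = ["HAHV", "HAHV", "LALV", "LAHV"]
        pred = ["HAHV", "LALV", "LALV", "LAHV"]
        cm = quadrant_confusion(truth, pred)
        assert cm.sum() == 4
        assert cm[0].sum() == 2  # two true HAHV
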