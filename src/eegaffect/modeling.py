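"""Regression, cross-validation, metrics and class mapping.

Separate models predict valence and arousal on the normalised [0, 1]
scale. The two retained regressors are 1-nearest-neighbour with the
Manhattan (L1) distance and a 500-tree random forest; linear, additive
(gradient boosting), decision-tree and SVR regressors are available as
baselines. Accuracy is reported with three measures over ground truth
y and predictions yhat of length N:

    MAE  = sum |yhat_i - y_i| / N
    RMSE = sqrt( sum (yhat_i - y_i)^2 / N )
    PCC  = Pearson correlation of (y, yhat)

Evaluation uses a seeded random 10-fold split over epochs ("subject
independent" in the sense of mixing all participants; an optional
grouped mode keeps all epochs of one subject in a single fold).
Predicted (valence, arousal) pairs are mapped to low/high halves at 0.5
(high inclusive) and to circumplex quadrants HAHV/HALV/LALV/LAHV;
binary accuracy is the macro average of per-class recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EEGAffectError, MetricUndefinedError
from .vectors import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegressorSpec",
    "AffectPrediction",
    "EvalReport",
    "metrics",
    "fit_predict_knn",
    "fit_predict_rf",
    "fit_predict",
    "make_folds",
    "cross_validate",
    "to_binary",
    "to_quadrant",
    "binary_accuracy",
    "quadrant_confusion",
    "QUADRANTS",
]

QUADRANTS = ("HAHV", "HALV", "LALV", "LAHV")

_BASELINE_KINDS = ("linear", "decision_tree", "additive", "svr_linear", "svr_rbf")


@dataclass(frozen=True)
class RegressorSpec:
    """A regressor kind plus its parameters.

    Defaults follow the tuned models: KNN with k=1 and the Manhattan
    distance; random forest with 500 trees.
    """

    kind: str = "knn"
    k: int = 1
    distance_metric: str = "manhattan"
    n_trees: int = 500
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "rf") + _BASELINE_KINDS:
            raise EEGAffectError(f"unknown regressor kind {self.kind!r}")


@dataclass(frozen=True)
class AffectPrediction:
    """A predicted (valence, arousal) pair on the normalised scale."""

    valence: float
    arousal: float


def metrics(y, yhat) -> tuple[float, float, float]:
    """(MAE, RMSE, PCC) of a prediction series against ground truth."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise EEGAffectError("metrics expects two equal-length series, n >= 2")
    err = yhat - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.var(y) == 0 or np.var(yhat) == 0:
        raise MetricUndefinedError("PCC undefined on a zero-variance series")
    n = y.size
    num = n * np.sum(yhat * y) - np.sum(yhat) * np.sum(y)
    den = np.sqrt(n * np.sum(yhat ** 2) - np.sum(yhat) ** 2) * np.sqrt(
        n * np.sum(y ** 2) - np.sum(y) ** 2
    )
    return mae, rmse, float(num / den)


def fit_predict_knn(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int = 1,
    distance_metric: str = "manhattan",
) -> np.ndarray:
    """k-nearest-neighbour regression with deterministic tie handling.

    Distance ties are broken by the lowest training-row index (stable
    sort over the distance row). ``train_y`` may be 1-D or column-stacked
    targets; predictions are the unweighted mean of the k neighbours.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=np.float64))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=np.float64))
    train_y = np.asarray(train_y, dtype=np.float64)
    if train_X.shape[0] == 0:
        raise EEGAffectError("empty training set")
    if k > train_X.shape[0]:
        raise EEGAffectError(f"k={k} exceeds training size {train_X.shape[0]}")
    metric = {"manhattan": "cityblock", "euclidean": "euclidean"}.get(
        distance_metric, distance_metric
    )
    dist = cdist(test_X, train_X, metric=metric)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return train_y[order].mean(axis=1)


def _make_sklearn_regressor(spec: RegressorSpec):
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.linear_model import LinearRegression
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    if spec.kind == "rf":
        return RandomForestRegressor(
            n_estimators=spec.n_trees, random_state=spec.seed, **spec.params
        )
    if spec.kind == "linear":
        return LinearRegression(**spec.params)
    if spec.kind == "decision_tree":
        return DecisionTreeRegressor(random_state=spec.seed, **spec.params)
    if spec.kind == "additive":
        return GradientBoostingRegressor(random_state=spec.seed, **spec.params)
    if spec.kind == "svr_linear":
        return SVR(kernel="linear", **spec.params)
    if spec.kind == "svr_rbf":
        return SVR(kernel="rbf", **spec.params)
    raise EEGAffectError(f"no sklearn mapping for {spec.kind!r}")


def fit_predict_rf(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Random-forest regression (bootstrap-aggregated trees), seeded."""
    from sklearn.ensemble import RandomForestRegressor

    train_y = np.asarray(train_y, dtype=np.float64)
    single = train_y.ndim == 1
    ys = train_y[:, None] if single else train_y
    preds = np.column_stack(
        [
            RandomForestRegressor(n_estimators=n_trees, random_state=seed)
            .fit(train_X, ys[:, j])
            .predict(test_X)
            for j in range(ys.shape[1])
        ]
    )
    return preds[:, 0] if single else preds


def fit_predict(
    spec: RegressorSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
) -> np.ndarray:
    """Dispatch one (train, predict) round for a single target series."""
    if spec.kind == "knn":
        return fit_predict_knn(train_X, train_y, test_X, spec.k, spec.distance_metric)
    if spec.kind == "rf":
        return fit_predict_rf(train_X, train_y, test_X, spec.n_trees, spec.seed)
    model = _make_sklearn_regressor(spec)
    return model.fit(train_X, np.asarray(train_y, dtype=np.float64)).predict(test_X)


def to_binary(pred: AffectPrediction, threshold: float = 0.5) -> tuple[str, str]:
    """(valence_class, arousal_class) with 'high' at or above threshold."""
    v = "high" if pred.valence >= threshold else "low"
    a = "high" if pred.arousal >= threshold else "low"
    return v, a


def to_quadrant(pred: AffectPrediction, threshold: float = 0.5) -> str:
    """Circumplex quadrant of a (valence, arousal) pair."""
    v, a = to_binary(pred, threshold)
    return {
        ("high", "high"): "HAHV",
        ("low", "high"): "HALV",
        ("low", "low"): "LALV",
        ("high", "low"): "LAHV",
    }[(v, a)]


def binary_accuracy(truth: list, predicted: list) -> float:
    """Macro-averaged per-class recall, in percent."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted) or not truth:
        raise EEGAffectError("class lists must align and be nonempty")
    classes = sorted(set(truth))
    if len(classes) < 2:
        raise EEGAffectError("binary accuracy needs both classes in the truth")
    recalls = []
    for c in classes:
        hits = sum(1 for t, p in zip(truth, predicted) if t == c and p == c)
        total = sum(1 for t in truth if t == c)
        recalls.append(hits / total)
    return 100.0 * float(np.mean(recalls))


def quadrant_confusion(truth: list, predicted: list) -> np.ndarray:
    """4x4 confusion counts, rows = true quadrant, order HAHV/HALV/LALV/LAHV."""
    index = {q: i for i, q in enumerate(QUADRANTS)}
    out = np.zeros((4, 4), dtype=int)
    for t, p in zip(truth, predicted):
        out[index[t], index[p]] += 1
    return out


@dataclass
class EvalReport:
    """Per-fold and aggregate regression metrics plus class accuracies."""

    per_fold: list[dict]  # {'valence': (mae, rmse, pcc), 'arousal': (...)}
    binary_accuracy: dict  # {'valence': %, 'arousal': %} or None values
    quadrant_confusion_matrix: np.ndarray
    n_clipped: int = 0

    def aggregate(self) -> dict:
        """Fold means of (MAE, RMSE, PCC) for each target."""
        out = {}
        for target in ("valence", "arousal"):
            arr = np.array([f[target] for f in self.per_fold])
            out[target] = tuple(arr.mean(axis=0))
        return out

    @property
    def quadrant_accuracy(self) -> float:
        total = self.quadrant_confusion_matrix.sum()
        if total == 0:
            raise MetricUndefinedError("empty confusion matrix")
        return 100.0 * float(np.trace(self.quadrant_confusion_matrix)) / float(total)

    def summary(self) -> str:
        agg = self.aggregate()
        lines = []
        for target in ("valence", "arousal"):
            mae, rmse, pcc = agg[target]
            lines.append(
                f"{target:8s} MAE={mae:.3f} RMSE={rmse:.3f} PCC={pcc:.3f}"
            )
        for target in ("valence", "arousal"):
            acc = self.binary_accuracy.get(target)
            if acc is not None:
                lines.append(f"{target:8s} binary accuracy = {acc:.1f}%")
        lines.append(f"quadrant accuracy = {self.quadrant_accuracy:.1f}%")
        return "\n".join(lines)


def make_folds(
    n_rows: int,
    n_folds: int,
    seed: int,
    groups: list | None = None,
) -> list[np.ndarray]:
    """Seeded random partition into near-equal folds (sizes differ <= 1).

    With ``groups`` given, whole groups are dealt round-robin in
    shuffled order so all rows of one group share a fold.
    """
    if n_folds < 2:
        raise EEGAffectError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    if groups is None:
        if n_folds > n_rows:
            raise EEGAffectError(f"{n_folds} folds for {n_rows} rows")
        perm = rng.permutation(n_rows)
        return [np.sort(part) for part in np.array_split(perm, n_folds)]
    unique = sorted(set(groups))
    if n_folds > len(unique):
        raise EEGAffectError(f"{n_folds} folds for {len(unique)} groups")
    order = rng.permutation(len(unique))
    assignment = {unique[g]: i % n_folds for i, g in enumerate(order)}
    folds = [[] for _ in range(n_folds)]
    for row, g in enumerate(groups):
        folds[assignment[g]].append(row)
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(
    matrix: FeatureMatrix,
    spec: RegressorSpec,
    n_folds: int = 10,
    seed: int = 0,
    group_by_subject: bool = False,
    folds: list[np.ndarray] | None = None,
) -> EvalReport:
    """Seeded k-fold cross-validation with separate valence/arousal models.

    Regression metrics are computed per fold on the raw predictions;
    class mappings use predictions clipped to [0, 1] pooled over all
    folds (every row predicted exactly once).
    """
    n = matrix.n_rows
    if folds is None:
        groups = matrix.subject_ids if group_by_subject else None
        folds = make_folds(n, n_folds, seed, groups)
    all_rows = np.concatenate(folds)
    if sorted(all_rows.tolist()) != list(range(n)):
        raise EEGAffectError("folds must partition the rows")

    pooled_pred = np.full((n, 2), np.nan)
    per_fold = []
    n_clipped = 0
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        fold_metrics = {}
        for j, target in enumerate(("valence", "arousal")):
            yhat = fit_predict(
                spec,
                matrix.X[train_mask],
                matrix.targets[train_mask, j],
                matrix.X[test_idx],
            )
            try:
                fold_metrics[target] = metrics(matrix.targets[test_idx, j], yhat)
            except MetricUndefinedError:
                mae = float(np.mean(np.abs(yhat - matrix.targets[test_idx, j])))
                rmse = float(np.sqrt(np.mean((yhat - matrix.targets[test_idx, j]) ** 2)))
                fold_metrics[target] = (mae, rmse, np.nan)
            n_clipped += int(np.count_nonzero((yhat < 0) | (yhat > 1)))
            pooled_pred[test_idx, j] = np.clip(yhat, 0.0, 1.0)
        per_fold.append(fold_metrics)
    if n_clipped:
        logger.info("%d predictions clipped to [0, 1]", n_clipped)

    true_pairs = [AffectPrediction(v, a) for v, a in matrix.targets]
    pred_pairs = [AffectPrediction(v, a) for v, a in pooled_pred]
    binary = {}
    for j, target in enumerate(("valence", "arousal")):
        truth_cls = ["high" if t >= 0.5 else "low" for t in matrix.targets[:, j]]
        pred_cls = ["high" if p >= 0.5 else "low" for p in pooled_pred[:, j]]
        try:
            binary[target] = binary_accuracy(truth_cls, pred_cls)
        except EEGAffectError:
            binary[target] = None
    confusion = quadrant_confusion(
        [to_quadrant(p) for p in true_pairs], [to_quadrant(p) for p in pred_pairs]
    )
    return EvalReport(
        per_fold=per_fold,
        binary_accuracy=binary,
        quadrant_confusion_matrix=confusion,
        n_clipped=n_clipped,
    )
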