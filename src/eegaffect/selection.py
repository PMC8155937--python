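"""Model-selection harness: wave-feature ranking, forward selection, sweeps.

The selection methodology evaluates every (wave, feature) pair as its
own single-pair vector (that feature on every channel of that band),
ranks pairs by cross-validated Pearson correlation, then adds them
greedily in ranked order until a new pair no longer improves the
criterion. Valence and arousal are selected independently, since
separate models predict them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EEGAffectError
from .modeling import RegressorSpec, cross_validate, make_folds
from .preprocessing import WAVE_ORDER
from .vectors import ALL_FEATURES, FeatureMatrix

__all__ = ["SelectionTrace", "rank_wave_features", "forward_select",
           "sweep_hyperparams"]

_TARGETS = ("valence", "arousal")


def _columns_for(matrix: FeatureMatrix, wave: str, feature: str) -> np.ndarray:
    cols = [
        i
        for i, c in enumerate(matrix.schema)
        if c["kind"] == "channel" and c["wave"] == wave and c["feature"] == feature
    ]
    return np.array(cols, dtype=int)


def _cv_pcc(
    matrix: FeatureMatrix,
    cols: np.ndarray,
    target: str,
    spec: RegressorSpec,
    folds: list[np.ndarray],
) -> float:
    report = cross_validate(matrix.select_columns(cols), spec, folds=folds)
    pccs = [f[target][2] for f in report.per_fold]
    return float(np.nanmean(pccs))


def rank_wave_features(
    matrix: FeatureMatrix,
    target: str,
    spec: RegressorSpec | None = None,
    waves: tuple[str, ...] | None = None,
    features: tuple | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> list[tuple[str, str, float]]:
    """Rank (wave, feature) pairs by cross-validated PCC, descending.

    Ties are broken deterministically by wave order (alpha, beta,
    gamma) then feature order. ``matrix`` must contain per-channel
    columns for every candidate pair.
    """
    if target not in _TARGETS:
        raise EEGAffectError(f"target must be one of {_TARGETS}")
    spec = spec or RegressorSpec()
    waves = waves or WAVE_ORDER
    features = features or tuple(f.value for f in ALL_FEATURES)
    features = tuple(getattr(f, "value", f) for f in features)
    folds = make_folds(matrix.n_rows, n_folds, seed)
    candidates = []
    for wi, wave in enumerate(waves):
        for fi, feature in enumerate(features):
            cols = _columns_for(matrix, wave, feature)
            if cols.size == 0:
                continue
            pcc = _cv_pcc(matrix, cols, target, spec, folds)
            candidates.append((wave, feature, pcc, wi, fi))
    if not candidates:
        raise EEGAffectError("no candidate (wave, feature) columns in matrix")
    candidates.sort(key=lambda c: (-c[2], c[3], c[4]))
    return [(w, f, p) for w, f, p, _, _ in candidates]


@dataclass
class SelectionTrace:
    """Record of one greedy forward-selection run."""

    target: str
    ranking: list[tuple[str, str, float]]
    accepted: list[tuple[str, str]] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)  # one entry per step
    stopping_reason: str = ""

    @property
    def final_pcc(self) -> float:
        accepted_steps = [h for h in self.history if h["accepted"]]
        return accepted_steps[-1]["pcc"] if accepted_steps else float("nan")


def forward_select(
    matrix: FeatureMatrix,
    ranking: list[tuple[str, str, float]],
    target: str,
    spec: RegressorSpec | None = None,
    improvement_epsilon: float = 0.001,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionTrace:
    """Greedy inclusion of ranked (wave, feature) pairs.

    Candidates join in ranking order; the first candidate whose
    inclusion fails to raise the cross-validated PCC by more than
    ``improvement_epsilon`` stops the search (first-failure stopping,
    not best-subset search). The trace records every evaluated step.
    """
    if not ranking:
        raise EEGAffectError("empty ranking")
    spec = spec or RegressorSpec()
    folds = make_folds(matrix.n_rows, n_folds, seed)
    trace = SelectionTrace(target=target, ranking=list(ranking))
    current_cols = np.array([], dtype=int)
    current_pcc = -np.inf
    for wave, feature, _ in ranking:
        cand_cols = np.concatenate([current_cols, _columns_for(matrix, wave, feature)])
        pcc = _cv_pcc(matrix, cand_cols, target, spec, folds)
        # the top-ranked candidate always enters (there is no empty model
        # to improve on); the stopping rule applies from the second on
        accepted = current_cols.size == 0 or pcc > current_pcc + improvement_epsilon
        trace.history.append(
            {"wave": wave, "feature": feature, "pcc": pcc, "accepted": accepted}
        )
        if not accepted:
            trace.stopping_reason = (
                f"({wave}, {feature}) did not improve PCC by > {improvement_epsilon}"
            )
            break
        trace.accepted.append((wave, feature))
        current_cols = cand_cols
        current_pcc = pcc
    else:
        trace.stopping_reason = "ranking exhausted"
    return trace


def sweep_hyperparams(
    matrix: FeatureMatrix,
    grid: dict[str, list],
    spec: RegressorSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Cross-validate one regressor over a parameter grid, paired folds.

    ``grid`` maps one parameter name (``k`` or ``n_trees``) to its
    values. The same seeded fold assignment is reused for every setting
    so settings are compared on identical train/test splits.
    """
    if len(grid) != 1:
        raise EEGAffectError("grid must sweep exactly one parameter")
    spec = spec or RegressorSpec()
    (param, values), = grid.items()
    if param not in ("k", "n_trees"):
        raise EEGAffectError("sweepable parameters: 'k', 'n_trees'")
    if not values:
        raise EEGAffectError("empty grid")
    folds = make_folds(matrix.n_rows, n_folds, seed)
    rows = []
    for value in values:
        setting = RegressorSpec(
            kind=spec.kind,
            k=value if param == "k" else spec.k,
            distance_metric=spec.distance_metric,
            n_trees=value if param == "n_trees" else spec.n_trees,
            seed=spec.seed,
            params=spec.params,
        )
        report = cross_validate(matrix, setting, folds=folds)
        agg = report.aggregate()
        row = {param: value}
        for target in _TARGETS:
            mae, rmse, pcc = agg[target]
            row[f"{target}_mae"] = mae
            row[f"{target}_rmse"] = rmse
            row[f"{target}_pcc"] = pcc
        rows.append(row)
    return rows
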