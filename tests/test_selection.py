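"""Wave-feature ranking, greedy forward selection and parameter sweeps."""

import numpy as np
import pytest

from eegaffect import (
    EEGAffectError,
    FeatureMatrix,
    RegressorSpec,
    forward_select,
    rank_wave_features,
    sweep_hyperparams,
)


def build_matrix(columns, n=60, seed=0, arousal_from=None, valence_from=None,
                 noise=0.05):
    """Hand-built feature matrix: ``columns`` is a list of (wave, feature);
    each becomes 2 channel-columns. Targets are driven by named columns."""
    rng = np.random.default_rng(seed)
    arousal = rng.uniform(0, 1, n)
    valence = rng.uniform(0, 1, n)
    X_cols, schema = [], []
    for wave, feature in columns:
        for ch in ("L", "R"):
            if (wave, feature) == arousal_from:
                col = arousal + noise * rng.standard_normal(n)
            elif (wave, feature) == valence_from:
                col = valence + noise * rng.standard_normal(n)
            else:
                col = rng.standard_normal(n)
            X_cols.append(col)
            schema.append(
                {"kind": "channel", "wave": wave, "channel": ch, "feature": feature}
            )
    return FeatureMatrix(
        X=np.column_stack(X_cols),
        schema=schema,
        targets=np.column_stack([valence, arousal]),
        subject_ids=[f"s{i % 3}" for i in range(n)],
        trial_ids=[f"t{i}" for i in range(n)],
        epoch_indices=list(range(n)),
    )


CANDIDATES = [("alpha", "SE"), ("beta", "H1"), ("gamma", "WP")]


class TestRanking:
    def test_informative_pair_ranked_first(self):
        m = build_matrix(CANDIDATES, arousal_from=("beta", "H1"))
        ranking = rank_wave_features(m, "arousal", n_folds=5, seed=1)
        assert ranking[0][:2] == ("beta", "H1")
        assert ranking[0][2] > 0.8

    def test_single_candidate_gives_length_one(self):
        m = build_matrix([("beta", "H1")], arousal_from=("beta", "H1"))
        ranking = rank_wave_features(
            m, "arousal", waves=("beta",), features=("H1",), n_folds=5, seed=1
        )
        assert len(ranking) == 1

    def test_duplicate_candidates_tie_broken_by_wave_then_feature_order(self):
        rng = np.random.default_rng(3)
        n = 40
        arousal = rng.uniform(0, 1, n)
        col = arousal + 0.05 * rng.standard_normal(n)
        schema = [
            {"kind": "channel", "wave": w, "channel": "L", "feature": "H1"}
            for w in ("alpha", "beta")
        ]
        m = FeatureMatrix(
            X=np.column_stack([col, col]),
            schema=schema,
            targets=np.column_stack([rng.uniform(0, 1, n), arousal]),
            subject_ids=["s0"] * n,
            trial_ids=[f"t{i}" for i in range(n)],
            epoch_indices=list(range(n)),
        )
        ranking = rank_wave_features(
            m, "arousal", waves=("alpha", "beta"), features=("H1",), n_folds=4, seed=0
        )
        assert ranking[0][2] == pytest.approx(ranking[1][2])
        assert ranking[0][0] == "alpha"  # wave order breaks the tie

    def test_unknown_target_rejected(self):
        m = build_matrix(CANDIDATES)
        with pytest.raises(EEGAffectError):
            rank_wave_features(m, "dominance")


class TestForwardSelection:
    def test_pure_noise_candidate_rejected_after_informative_set(self):
        m = build_matrix(CANDIDATES, arousal_from=("beta", "H1"), seed=5)
        ranking = rank_wave_features(m, "arousal", n_folds=5, seed=1)
        trace = forward_select(m, ranking, "arousal", n_folds=5, seed=1)
        assert ("beta", "H1") in trace.accepted
        rejected = [h for h in trace.history if not h["accepted"]]
        assert rejected, "noise candidates should stop the search"
        assert trace.stopping_reason

    def test_infinite_epsilon_keeps_only_top_candidate(self):
        m = build_matrix(CANDIDATES, arousal_from=("beta", "H1"), seed=6)
        ranking = rank_wave_features(m, "arousal", n_folds=5, seed=1)
        trace = forward_select(
            m, ranking, "arousal", improvement_epsilon=np.inf, n_folds=5, seed=1
        )
        assert trace.accepted == [ranking[0][:2]]

    def test_duplicate_informative_columns_keep_exactly_one(self):
        rng = np.random.default_rng(9)
        n = 60
        arousal = rng.uniform(0, 1, n)
        col = arousal + 0.05 * rng.standard_normal(n)
        schema = [
            {"kind": "channel", "wave": w, "channel": "L", "feature": "H1"}
            for w in ("alpha", "beta", "gamma")
        ]
        m = FeatureMatrix(
            X=np.column_stack([col, col, col]),
            schema=schema,
            targets=np.column_stack([rng.uniform(0, 1, n), arousal]),
            subject_ids=["s0"] * n,
            trial_ids=[f"t{i}" for i in range(n)],
            epoch_indices=list(range(n)),
        )
        ranking = rank_wave_features(m, "arousal", features=("H1",), n_folds=5, seed=2)
        trace = forward_select(m, ranking, "arousal", n_folds=5, seed=2)
        assert len(trace.accepted) == 1

    def test_accepted_pcc_never_decreases_with_zero_epsilon(self):
        m = build_matrix(
            CANDIDATES + [("gamma", "H1")],
            arousal_from=("beta", "H1"),
            seed=10,
        )
        ranking = rank_wave_features(m, "arousal", n_folds=5, seed=3)
        trace = forward_select(
            m, ranking, "arousal", improvement_epsilon=0.0, n_folds=5, seed=3
        )
        accepted_pccs = [h["pcc"] for h in trace.history if h["accepted"]]
        assert accepted_pccs == sorted(accepted_pccs)

    def test_empty_ranking_rejected(self):
        m = build_matrix(CANDIDATES)
        with pytest.raises(EEGAffectError):
            forward_select(m, [], "arousal")


class TestSweep:
    def test_grid_rows_and_determinism(self):
        m = build_matrix(CANDIDATES, arousal_from=("beta", "H1"), seed=11)
        t1 = sweep_hyperparams(m, {"k": [1, 3]}, n_folds=5, seed=4)
        t2 = sweep_hyperparams(m, {"k": [1, 3]}, n_folds=5, seed=4)
        assert len(t1) == 2
        assert t1 == t2

    def test_k1_beats_k21_on_low_noise_data(self):
        m = build_matrix(
            CANDIDATES, arousal_from=("beta", "H1"),
            valence_from=("gamma", "WP"), n=120, noise=0.02, seed=12,
        )
        table = sweep_hyperparams(m, {"k": [1, 21]}, n_folds=5, seed=4)
        by_k = {row["k"]: row for row in table}
        assert by_k[1]["arousal_mae"] <= by_k[21]["arousal_mae"]

    def test_multi_parameter_grid_rejected(self):
        m = build_matrix(CANDIDATES)
        with pytest.raises(EEGAffectError):
            sweep_hyperparams(m, {"k": [1], "n_trees": [10]})
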