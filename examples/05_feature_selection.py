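"""Rank wave-feature pairs by cross-validated PCC and select greedily.

Reproduces the selection methodology at desk scale: every (wave,
feature) pair is tried as its own vector, pairs are ranked by PCC, and
a model grows by adding pairs in ranked order until the next pair stops
improving the correlation.
"""

from eegaffect import RegressorSpec, builtin_montage, segment_epochs
from eegaffect.selection import forward_select, rank_wave_features
from eegaffect.synthetic import generate, strong_recovery_config
from eegaffect.vectors import ALL_FEATURES, builtin_config, assemble
from dataclasses import replace

from eegaffect.vectors import VectorConfig

config = replace(strong_recovery_config(seed=2), n_trials=24)
trials = generate(config)
epochs = [ep for t in trials for ep in segment_epochs(t.recording, 4.0, 0.0)]
all_waves = VectorConfig(
    montage=config.montage,
    waves=("alpha", "beta", "gamma"),
    features_per_wave={w: ALL_FEATURES for w in ("alpha", "beta", "gamma")},
)
matrix = assemble(epochs, all_waves)

features = ("H1", "WP", "SE")  # a small candidate pool keeps this quick
ranking = rank_wave_features(
    matrix, target="arousal", spec=RegressorSpec(kind="knn"),
    features=features, n_folds=5, seed=0,
)
print("arousal ranking (wave, feature, cross-validated PCC):")
for wave, feature, pcc in ranking:
    print(f"  {wave:6s} {feature:4s} {pcc:+.3f}")

trace = forward_select(
    matrix, ranking, target="arousal", spec=RegressorSpec(kind="knn"),
    n_folds=5, seed=0,
)
print("\naccepted pairs:", trace.accepted)
print("stopping reason:", trace.stopping_reason)
print(f"final PCC: {trace.final_pcc:+.3f}")

# Arousal is encoded in the beta/gamma amplitudes, so beta/gamma energy
# features (H1, WP) should top the ranking while alpha spectral entropy
# contributes nothing and is refused by the forward step.
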