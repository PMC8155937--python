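"""Cross-validated recovery of latent valence/arousal from synthetic EEG.

Runs the full pipeline (generate -> segment -> condition -> extract ->
10-fold KNN regression) under strong-signal conditions, then with the
affect gains zeroed. The first run should recover the latents almost
perfectly; the second calibrates the harness: with no signal in the
recordings the correlations must hover around zero.
"""

from eegaffect import RegressorSpec, builtin_config, builtin_montage
from eegaffect.synthetic import (
    null_config,
    recovery_experiment,
    strong_recovery_config,
)

montage = builtin_montage("emotiv14")
vector_config = builtin_config("knn_selected", montage)

print("strong signal, low noise:")
report = recovery_experiment(
    strong_recovery_config(seed=11), vector_config,
    RegressorSpec(kind="knn"), n_folds=10, seed=3,
)
print(report.summary())

print("\nnull (gains zeroed):")
report = recovery_experiment(
    null_config(seed=11), vector_config,
    RegressorSpec(kind="knn"), n_folds=10, seed=3,
)
agg = report.aggregate()
for target in ("valence", "arousal"):
    print(f"{target:8s} PCC={agg[target][2]:+.3f}  "
          "(single-seed estimate; averages to ~0 over seeds)")

# Under the strong configuration PCC approaches 1 and the MAE is below
# 0.02 on the [0, 1] scale; under the null the correlations are noise
# around zero, confirming the evaluation measures signal, not leakage.
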