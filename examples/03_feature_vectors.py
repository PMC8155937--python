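"""Assemble named feature-vector configurations and check their sizes.

The two selected models: a KNN vector (all features except spectral
entropy from the three bands, plus the alpha differential asymmetry
without H3) and a leaner RF vector (H1 + wavelet energy from beta and
gamma, plus three alpha-asymmetry features).
"""

from eegaffect import builtin_config, builtin_montage, segment_epochs
from eegaffect.synthetic import GeneratorConfig, generate
from eegaffect.vectors import assemble

for montage_name in ("deap32", "emotiv14"):
    montage = builtin_montage(montage_name)
    for name in ("knn_selected", "rf_selected", "full_per_band",
                 "asym_differential"):
        config = builtin_config(name, montage)
        print(f"{name:18s} on {montage_name:9s} -> {config.dimension:4d} features")

montage = builtin_montage("emotiv14")
trials = generate(GeneratorConfig(montage=montage, n_trials=4,
                                  trial_seconds=4.0, seed=1))
epochs = [ep for t in trials
          for ep in segment_epochs(t.recording, 4.0, 0.0)]
matrix = assemble(epochs, builtin_config("rf_selected", montage))
print(f"\nassembled matrix: {matrix.X.shape[0]} epochs x "
      f"{matrix.X.shape[1]} features")
print("first three columns:", matrix.column_names()[:3])
print("last column:        ", matrix.column_names()[-1])

# Column order is fixed: waves outermost, channels in montage order,
# features innermost, with the asymmetry block (pair x feature) last.
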