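"""Generate synthetic affect-labelled EEG trials and cut them into epochs.

Each trial is a 14-channel, 8 s recording whose beta/gamma amplitudes
grow with a latent arousal value and whose left-right alpha balance
shifts with latent valence. Epochs inherit the trial's labels.
"""

from eegaffect import GeneratorConfig, builtin_montage, segment_epochs
from eegaffect.synthetic import generate

config = GeneratorConfig(
    montage=builtin_montage("emotiv14"),
    n_trials=8,
    trial_seconds=8.0,
    seed=42,
)
trials = generate(config)

print(f"{len(trials)} trials, montage {config.montage.name} "
      f"({config.montage.n_channels} channels, {config.montage.n_pairs} pairs)")
for trial in trials[:4]:
    rec = trial.recording
    epochs = segment_epochs(rec, epoch_seconds=4.0, overlap_fraction=0.5)
    print(
        f"  {rec.trial_id}: valence={trial.true_valence:.2f} "
        f"arousal={trial.true_arousal:.2f} -> {len(epochs)} epochs of 4 s"
    )

# An 8 s trial with 4 s windows and 50 % overlap yields 3 epochs
# (starts at 0, 2 and 4 s); all carry the same (valence, arousal) pair,
# because self-reports refer to the whole stimulus.
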