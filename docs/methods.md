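# Methods

This note documents the models, parameter choices and numerical
decisions behind `eegaffect`, and what the synthetic test-bed does and
does not establish about real EEG.

## Data model and label scale

A recording is one participant-trial, channels × samples in microvolts,
with channels ordered by a named montage (`deap32`: the Biosemi
32-electrode layout with 14 homologous left–right pairs; `emotiv14`:
the Emotiv EPOC layout, 7 pairs — all pairs are 10–20 homologues such
as F3–F4). Self-assessment ratings arrive on a source scale
(default the 9-point SAM scale, `[1, 5]` selectable) and are mapped
affinely to [0, 1]; all prediction errors are reported on that
normalised scale, so an MAE of 0.06 means 6 % of the rating range. The
affine map is exactly invertible, which the tests verify to 1e-12.

Epochs are fixed windows (default 4 s, 50 % overlap) starting at
`0, hop, 2·hop, …` with `hop = epoch_seconds · (1 − overlap)`. A
trailing partial window is dropped rather than padded: zero-padding
would bias every spectral feature of the final epoch. All epochs of a
trial carry the trial's labels, since self-reports refer to the whole
stimulus.

## Conditioning chain

Per channel: linear detrend → IIR notch at 50 Hz (Q = 30, applied
forward–backward) → wavelet-threshold artifact suppression. Band
extraction uses windowed-sinc (Hamming) FIR band-pass filters,
order 129 at fs = 128, also applied forward–backward. Zero-phase
application was chosen so band-limited features stay aligned with the
epoch grid; the squared magnitude response only sharpens band
selectivity. Order 129 keeps the filter's edge transients to about one
second, acceptable inside 4 s epochs; the cost is a transition band of
roughly ±1.5 Hz, so passband properties (unit gain, idempotence) hold
in the band interior rather than at the nominal edges.

The gamma band is 30–45 Hz. Physiologically gamma is open-ended above
30 Hz, but the 50 Hz power-line notch and the 128 Hz sampling of
typical affective-EEG recordings force an upper edge below the notch.

### Ocular-artifact suppression

`suppress_eog` decomposes the signal with a 4-level periodised db4 DWT
and thresholds at the universal level `λ = σ·sqrt(2 ln N)`. Two rules
are provided:

* **`clip` (default).** σ is estimated robustly per scale
  (MAD/0.6745), the approximation included, and coefficient magnitudes
  are clipped to λ. Ocular artifacts are large slow excursions whose
  energy sits in *outlier* coefficients at coarse scales; ongoing
  oscillations set each scale's typical magnitude and pass through.
  On a 10 Hz test oscillation with a superimposed blink-like pulse this
  removes about two-thirds of the artifact RMSE.
* **`soft`.** Classical denoising shrinkage (σ from the finest detail
  scale, soft rule on all detail scales). This was the initial design,
  but measurement showed it is the wrong tool for artifact suppression:
  soft shrinkage subtracts λ from *every* coefficient, which biases
  sustained oscillations (not sparse in the wavelet domain) while
  barely denting a large transient. It is kept for what it is good at —
  removing broadband noise from wavelet-sparse signals.

Adaptive (reference-based) ECG filtering is a config hook only; it
requires an ECG reference channel that the feature pipeline does not
use, and enabling it raises `NotImplementedError`.

## Features

Eight features per channel and band. Hjorth parameters and spectral
entropy are computed on the band-passed signal; wavelet and IMF
features on the broadband conditioned signal, because the DWT and EMD
are themselves band-limited decompositions.

Numerical conventions, chosen where the definitions leave freedom:

* The derivative in mobility/complexity is the first difference
  (length N−1); variances are population-style. On a sampled sine the
  finite-difference mobility is `2 sin(π f / fs)`, within 2 % of the
  continuous limit `2π f / fs` for `fs/f ≥ 32`, which the tests pin.
* The PSD for spectral entropy is the magnitude-squared DFT of the
  mean-removed signal over positive-frequency bins, no taper, with
  `0·log2 0 ≡ 0`. A rectangular window keeps an integer-period tone in
  one bin, so two equal tones give 1 bit exactly; a Hann taper would
  spread each tone over three bins and add more than a bit of
  window-induced entropy.
* The DWT uses periodisation, making the transform orthogonal:
  Parseval's identity holds to float precision and is asserted at 1e-6.
  Wavelet entropy is the Shannon entropy of the squared coefficients
  *within the band's own level* (the plausible alternative — entropy
  over relative level energies — would give one number per signal, not
  per band).
* Degenerate inputs (constant signal, zero spectral energy, missing
  IMF, zero right-hemisphere value under rational asymmetry) raise
  typed `FeatureUndefinedError`s; vector assembly records such entries
  as 0 with a flag count, keeping matrices rectangular and NaN-free.

### Empirical mode decomposition

Sifting follows the classical recipe: strict local extrema (plateau
runs counted once at their midpoint), cubic-spline upper/lower
envelopes through maxima/minima with the two extrema nearest each
boundary mirrored across it (this anchors the spline and prevents end
swings), envelope-mean subtraction repeated until the candidate
satisfies the IMF conditions (extrema and zero-crossing counts differ
by ≤ 1) and the Cauchy-type criterion
`SD = Σ(h_prev − h_cur)² / Σ h_prev² < 0.2`, with a hard cap of 100
sift iterations. Outer extraction stops when the residue has at most
one extremum or after `max_imfs` (default 10) components. Completeness
`x = Σ c_i + r_N` is exact by construction because the residue is
updated by subtraction; the acceptance suite still measures it on 200
random signals. The 0.2 threshold is the conventional default; the
sifting cap guards against pathological non-convergence on noise.

## Feature vectors

Column order is deterministic and documented: waves outermost (alpha,
beta, gamma), channels in montage order, features innermost; the
asymmetry block is appended last (differential before rational when
both modes are used), pairs outer, features inner. The built-in
configurations reproduce the selected models' dimensionalities —
770/343 (KNN vector on 32/14 channels), 170/77 (RF vector), 256 (all
eight features of one band on 32 channels) and 112 (all eight features
over the 14 pairs for a single asymmetry mode; the concatenation of
both modes is 224).

No feature standardisation is applied before KNN — distances are
Manhattan on raw feature values, matching default-tool usage; a config
switch can reintroduce scaling.

## Regression and evaluation

KNN is implemented directly (L1 distances via `scipy.spatial.cdist`, a
stable argsort) so the tie rule — lowest training-row index — is
guaranteed rather than an artifact of library internals; sklearn's
`KNeighborsRegressor` serves as an independent cross-check in the
tests. The random forest and the baseline regressors (linear,
gradient-boosting "additive", decision tree, SVR with linear and RBF
kernels) are sklearn estimators behind the module's interface, seeded
for bitwise reproducibility.

Cross-validation partitions epochs into seeded random near-equal folds
("subject-independent" in the sense of mixing all participants into
one pool). Because epochs of one subject can land in different folds,
an optional grouped mode deals whole subjects into folds instead; both
are exposed, no position is taken on which better matches the term.
Per-fold MAE/RMSE/PCC are computed on raw predictions; aggregate
metrics are fold means. For class mappings, predictions are clipped to
[0, 1] (clip counts logged; PCC is computed before clipping, since
clipping is a monotone distortion that would flatter correlation).
The binary cut is 0.5 — the midpoint of the normalised scale — with
"high" inclusive; quadrants (HAHV/HALV/LALV/LAHV) follow from the two
binary labels, and binary accuracy is the macro average of per-class
recall, so a constant classifier scores 50 % regardless of class
balance.

Feature selection ranks each (wave, feature) pair by the
cross-validated PCC of a model using only that pair's channel columns,
then adds pairs greedily in ranked order. The top pair always enters
(there is no empty model to improve on); from the second pair on, a
candidate must raise PCC by more than `improvement_epsilon`
(default 0.001) or the search stops at the first failure — one-by-one
inclusion, not best-subset search, and the initial ranking is not
recomputed after inclusions. Valence and arousal are selected
independently since separate models predict them. Hyperparameter
sweeps reuse one seeded fold assignment across all settings (paired
comparison).

## Synthetic test-bed

Each trial draws a latent (valence, arousal) pair — uniform per
circumplex quadrant by default, or on a grid — and synthesises every
channel as pink noise (1/f-shaped spectrum) plus three sinusoids with
independent random phases per channel. Beta and gamma amplitudes are
affine in arousal on both hemispheres (`base 1.25, gain 1.0` by
default; the reference recovery conditions use gain 1.5 and noise SD
0.3 — a ±75 % amplitude swing, oscillations well above the noise
floor). The alpha amplitudes of homologous pair members move in
opposite directions with valence, following the valence hypothesis
(left-hemisphere dominance for positive affect, expressed as lower
left-relative alpha power at high valence), so the differential alpha
asymmetry of H1 correlates *negatively* with valence by construction.

Two deliberate choices matter for honest evaluation:

* **Oscillator frequencies 10.1 / 19.9 / 38.3 Hz.** At the exact
  subband centres 10/20/38 Hz every frequency completes an integer
  number of cycles in a 4 s epoch, so all epochs of a trial see the
  identical oscillation phase. Phase-sensitive features (DWT and EMD
  energies) then fingerprint the trial, and a 1-NN model matches
  same-trial epochs — inflating correlations to ~0.4 even with both
  gains at zero. Non-commensurate frequencies (still inside the
  8–16/16–32/32–64 Hz subbands) decorrelate the phases across epochs
  and restore a clean null.
* **Non-overlapping epochs in `recovery_experiment`.** Overlapping
  windows share half their raw samples; the nearest neighbour of an
  epoch is then almost always its overlapping same-trial neighbour,
  which carries the same label. The null calibration would measure
  sample sharing, not type-I behaviour. Real-data segmentation keeps
  the 4 s / 50 % default; the recovery harness defaults to overlap 0.

The reference recovery conditions (40 trials × 8 s → 80 epochs,
14-channel montage, 10 folds) keep the full acceptance run around two
minutes on one CPU while leaving ample signal: under them the KNN
model attains PCC > 0.99 for both targets, and the null configuration
averages |PCC| < 0.05 over five generator seeds. A single null run of
80 epochs has fold-level PCC sampling noise of roughly 0.1 SD, so the
calibrated quantity is the five-seed average.

What the synthetic results do **not** show: the generator has no 1/f
exponent variation, no evoked responses, no volume conduction, no
inter-subject variability, and its affect encoding is exactly the
monotone amplitude coupling the features were designed to detect.
Passing recovery therefore validates the pipeline's mechanics
(conditioning, feature math, vector layout, evaluation) — it says
nothing about effect sizes in real EEG, and results on the restricted
affective datasets cannot be inferred from it.

## Known limitations

* EDF input requires the optional `mne` dependency; labels must come
  from a side table since EDF carries none.
* The DWT band mapping assumes `fs = 128·2^k`; other rates would shift
  the subband edges away from the conventional bands.
* EMD mode mixing on noisy signals blurs the IMF→band correspondence;
  the IMF features are complementary to, not substitutes for, the
  wavelet features.
* Rational asymmetry is undefined when the right-hemisphere feature is
  exactly zero; such entries are flagged and zero-filled.
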