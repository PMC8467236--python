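# Methods

## Signal model and scope

The package treats a subject as one single-channel EEG recording with a
binary label (apnea / normal). Labels are taken as given via a sidecar
table; no respiratory channels, hypnograms, or AHI computation are
involved. Recordings are processed in 30 s epochs — the sleep-scoring
convention — and a trailing partial epoch is discarded rather than
zero-padded, so every epoch of a recording yields coefficient vectors of
identical length.

## Notch preprocessing

Mains interference is removed with a second-order IIR notch designed from
a center frequency f0 (default 50 Hz; 60 Hz selectable) and quality factor
Q (default 30, i.e. a ≈1.7 Hz stopband at 50 Hz). The filter is applied
forward-backward (zero phase), so epochs stay phase-aligned for the
wavelet stage. No band-pass, ICA, or artifact rejection is applied: the
pipeline's only preprocessing claim is mains suppression. Filter order, Q,
and zero-phase application are defaults of this implementation, exposed in
the configuration.

## Wavelet-packet band decomposition

A depth-L wavelet packet transform (default wavelet db8; PyWavelets
backend) splits [0, fs/2) into 2^L sub-bands of width fs/2^(L+1). Two
details are load-bearing and easy to get wrong:

- **Sequency ordering.** The filter cascade emits terminal nodes in
  natural (Paley) order, which interleaves frequencies. Nodes are permuted
  by the binary-reflected Gray code before any frequency interpretation;
  the permutation is cross-checked in the tests both against PyWavelets'
  frequency-ordered traversal and physically, by probing each slot with a
  pure tone and asserting where its energy lands.
- **Depth selection.** The literal 3-level tree gives 12.5 Hz sub-bands at
  200 Hz — delta, theta and most of alpha share one node and cannot be
  separated. The default depth is therefore automatic: the smallest L with
  sub-bands ≤ 2 Hz (L = 5 at 100 Hz, 6 at 200 Hz, 7 at 512 Hz), which
  resolves the delta/theta boundary at every clinical rate. An explicit
  shallow level is honored for literal runs but triggers a warning.

Each sub-band is assigned to the EEG band (delta < 4, theta 4–8, alpha
8–13, beta 14–32, gamma > 32 Hz, Nyquist-capped) with which its interval
overlaps most; ties break toward the lower band, and the 13–14 Hz gap
between the nominal alpha and beta edges is absorbed by the same rule. A
band lying entirely above Nyquist receives an empty coefficient vector.

Boundary handling defaults to periodization, which makes the transform
orthogonal in the strict sense: total coefficient energy equals signal
energy to machine precision for dyadic-length inputs (asserted at 1e-8 in
the tests). For non-dyadic lengths (a 30 s epoch at 200 Hz is 6000
samples) odd intermediate lengths are padded, inflating total energy by
roughly 0.2% at depth 6; this bias is shared by all bands and does not
affect classification, but exact-conservation checks use dyadic lengths.

## Features

Per band, two scalars:

- **Energy** E = Σᵢ pᵢ², the sum of squared band coefficients (µV² scale).
- **Entropy** H = −Σᵢ qᵢ ln qᵢ with qᵢ = pᵢ²/Σⱼ pⱼ², i.e. Shannon entropy
  of the normalized coefficient energy distribution, with 0·ln 0 := 0.
  The normalization makes H scale-invariant and bounded in [0, ln N];
  an unnormalized variant would depend on amplitude units and could be
  negative. The log base is configurable (natural by default). An all-zero
  band has H = 0 (degenerate point distribution).

Four band-energy ratios complete the 14-vector: θ/α ("heart rate"),
α/δ ("brain perfusion"), β/θ ("neural activity"), δ/θ ("synchronization").
The ratio inputs are band energies; denominators carry an additive guard
of 1e-12 so degenerate all-zero inputs flow through as 0 rather than
erroring. Per-epoch vectors are averaged per recording by default — one
row per subject, matching subject-level evaluation — with a per-epoch mode
available. Aggregation level is a design choice of this package.

## Classification and evaluation

- **SVM** (linear, RBF, polynomial order 2 and 3; C = 1.0, coef0 = 1,
  gamma = 1/(n_features·Var)) on standardized features. Standardization
  statistics are estimated on training data only (asserted by a dedicated
  anti-leakage test); unscaled energies span orders of magnitude and would
  dominate kernel distances. The polynomial order-2 kernel is the default.
- **Random forest**: 150 trees, bootstrap with 2/3 of the training set
  in-bag, out-of-bag error always reported, raw (unstandardized) features.
- **Evaluation**: a stratified 90/10 hold-out split and stratified 10-fold
  cross-validation are both always computed and reported separately. The
  split takes floor(0.9·n) subjects per class for training, so an
  89-subject cohort with 57/32 class counts splits 79/10. Metrics are
  accuracy, sensitivity (TP/(TP+FN)) and specificity (TN/(TN+FP)) with
  apnea as the positive class; an undefined denominator yields NaN with a
  warning, never a silent 0. All splits, folds, and forests are
  deterministic for a fixed seed.

## Synthetic cohorts

Each synthetic recording is a sum of per-band components: white Gaussian
noise filtered to the band's range (4th-order Butterworth, zero-phase),
scaled to RMS ∝ √(relative band power), plus an optional 50 Hz sinusoid
and broadband white noise. Band-limited noise rather than pure tones keeps
the entropy features informative. The default class contrast — apnea-like
profile (δ, θ, α, β, γ) = (3.0, 2.0, 0.5, 0.3, 0.1), normal profile
(0.8, 0.6, 2.5, 1.8, 0.3) — is an explicit synthetic convention chosen to
be well separated, not a physiological claim. Per-recording lognormal
jitter (σ = 0.2) on each band power creates within-class variability.
Cohort generation is fully seeded via spawned seed sequences.

What the generator does **not** emulate: sleep architecture (stages,
spindles, K-complexes), apnea event morphology, nonstationarity, movement
or ocular artifacts, inter-channel structure. Passing tests on synthetic
cohorts therefore demonstrate that the pipeline recovers class-conditional
band-power contrasts it was fed — they do not certify clinical accuracy on
real polysomnography.

## Numerical and design notes

- EDF is read through mne; EDF export uses a small built-in plain-EDF
  writer (16-bit, 1 s records, symmetric physical range), so round-trip
  quantization error is ≤ the 16-bit grid (relative L2 error ~1e-5 for a
  unit sinusoid).
- Chance-level checks use the 95% binomial interval around 0.5 on the
  evaluated sample count. Cross-validated accuracy under the null is
  unbiased (mean ≈ 0.5 over seeds) but overdispersed relative to the
  binomial width, since folds share training data; single-seed null values
  outside ±2·binomial-SE occasionally occur by construction.
- Problem sizes in tests and the acceptance script (cohorts of 30–40
  recordings, 100 Parseval epochs, 15 tone probes) are chosen so the whole
  suite runs in well under a minute while keeping every statistical check
  at a scale where its expected behavior is unambiguous.
- Known limitations: no best-basis tree selection, no undecimated WPD, no
  hyperparameter search, no ROC/AUC; multi-channel fusion is out of scope
  (one channel per run).
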