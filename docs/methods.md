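# Methods

This note documents the models and procedures implemented in `doafuse`,
the parameter choices that matter, and what the synthetic experiments do
and do not establish.

## Signal model of the synthetic generator

Each anesthesia state is a `StateSpec`: relative band powers over the
canonical EEG bands (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–47 Hz), a list of quadratically phase-coupled triads
(f₁, f₂, strength), a burst-suppression fraction, and a reference-index
interval inside the state's 0–100 band (awake [80, 100], light [60, 80),
general [40, 60), deep [0, 40)).

The signal is the simplest construction that exposes every property the
estimators measure:

* **Band structure** — per band, white Gaussian noise filtered by a
  4th-order Butterworth band-pass, normalized to unit variance and scaled
  by √(weight); the weighted sum has band-power proportions within ±0.1
  of the requested weights over 60 s (verified by Welch estimates in the
  tests).
* **Phase coupling** — each triad adds cosines at f₁, f₂ and f₁+f₂ with
  φ₃ = φ₁ + φ₂, which produces a bispectral peak at (f₁, f₂); amplitude
  is `0.5·strength` relative to the unit-variance noise mixture.
* **Burst suppression** — a multiplicative envelope alternating between 1
  and 0.005, exponentially distributed segment lengths (mean burst 2 s,
  suppression mean chosen so the long-run suppressed fraction matches the
  spec), edges smoothed over 50 ms to avoid broadband clicks.  The
  envelope's low level is small enough that a fully suppressed record is
  near-isoelectric (RMS < 1% of the unsuppressed signal).
* **Scale** — clean RMS fixed at 20 µV (typical frontal EEG), measured
  over unsuppressed samples so suppression genuinely lowers amplitude.

A patient is an ordered profile of (state, minutes): segments are
concatenated with 1-s cross-fades; the per-minute reference index is
drawn inside each state's interval, smoothed with a 3-minute moving
average (reference monitors trend smoothly), then clipped back into the
state band so `classify_state(ref[i])` always equals the label.

Artifact injection adds, at configurable events-per-minute rates:
monophasic ~1 s Hanning-squared ocular deflections (120–250 µV, spectral
content below 4 Hz), 0.5-s Hanning-tapered broadband muscle bursts
(high-passed above 30 Hz, 10× signal RMS), and single-sample spikes at
10 SD.  The clean record and event stamps are returned so removal can be
scored against ground truth.

**What the generator does not emulate:** pharmacokinetics, electrode
artifacts, non-stationarity within a state, inter-patient spectral
variability, mains interference, or the real covariance structure of
clinical EEG.  Passing tests demonstrate estimator and pipeline
correctness under the stated statistical assumptions — not clinical
performance.

## Preprocessing chain

Order: outlier removal → FIR band-pass → SWT ocular suppression → AR
inverse-filter muscle repair → resample to 100 Hz → 1-min epochs.

* **Outliers** — samples beyond mean ± k·SD of a centered 10-s sliding
  window (k = 6) are linearly interpolated.  k = 6 keeps the false-flag
  probability for Gaussian EEG near 2·10⁻⁹ per sample, so clean signal is
  essentially never touched; constant stretches (SD = 0) are exempt.
* **FIR** — 513-tap Hamming band-pass 0.5–47 Hz at 128 Hz input.  513
  taps give a ~0.8 Hz transition, ≥ 40 dB at 0.1 Hz (drift) and ≥ 40 dB
  at 55 Hz (mains); applied in one forward pass on a reflection-padded
  signal with the constant group delay removed, so the linear-phase
  property is preserved exactly — relative phase matters downstream
  because the bispectrum is a phase-sensitive statistic.
* **SWT** — stationary wavelet transform, `coif3`, 6 levels.  Ocular
  artifacts are high-amplitude and concentrated below ~4 Hz, i.e. in the
  approximation and the two coarsest detail levels at these rates; in
  those levels only, coefficients beyond the universal threshold
  σ√(2 ln N) (σ from the level's MAD) are clipped to the threshold.
  Fine-scale levels pass untouched, so ongoing rhythms are preserved
  (clean-signal correlation ≥ 0.99 in tests).
* **Inverse filter** — an AR(10) model (Burg) fit to the whole record
  whitens it; local residual RMS (25 ms window) beyond 5 robust SDs flags
  transients, and flagged segments are replaced by cross-faded
  forward/backward AR prediction.  AR order 10 is ample for the 0.5–47 Hz
  EEG spectrum; the residual threshold flags ≤ 1% of stationary signal
  while catching ≥ 80% of a 10× RMS broadband burst.
* **Resampling** — polyphase rational resampling (e.g. 128→100 Hz =
  ×25/32); passband content below 47 Hz is preserved within 2%.
* **Epoching** — non-overlapping 6000-sample minutes; a minute in which
  more than 25% of samples were corrected upstream is excluded.  The 25%
  budget is a design choice: below it, interpolated stretches have little
  effect on the four features; above it, the minute is better treated as
  unusable (this is also why a cleaned record can contain fewer usable
  minutes than the raw one).

Whether artifact samples should be repaired or their minutes deleted is
genuinely open; both behaviors are available (the exclusion budget is
configurable down to 0, which reduces to whole-minute deletion).

## Features

* **PE** — m = 3, τ = 1, N = 1000 (10 s at 100 Hz), six windows averaged
  per minute.  Ordinal patterns are encoded by the Lehmer code of the
  stable argsort, so ties break earliest-index-first; continuous signals
  make ties rare, but determinism requires a rule.  Natural logarithms
  cancel in the normalization by ln(m!).  m = 3 is the default operating
  point; m up to 6 is supported for parameter studies.
* **Welch PSD** — 4-s Hann segments, 50% overlap: 0.25 Hz resolution and
  ~29 averages inside one epoch, a reasonable variance/resolution
  balance.  Band sums include bins whose center lies in [lo, hi].
* **BR** — log base 10 (any fixed base only rescales an input to the
  network; 10 is the convention in this literature).  A power floor of
  1e−12 µV² guards empty bands; a both-bands-empty spectrum returns 0
  with a degeneracy flag.
* **SEF95** — cumulative in-band power with linear interpolation inside
  the crossing bin.
* **Bispectrum** — direct method: per 256-sample Hann segment (50%
  overlap), `B_s(f₁,f₂) = X_s(f₁)X_s(f₂)X*_s(f₁+f₂)`, averaged over
  segments on the principal domain 0 ≤ f₂ ≤ f₁, f₁+f₂ ≤ Nyquist.
  Averaging preserves coupled triads (segment bispectra align in phase)
  and suppresses incoherent background.
* **SFS** — band limits 0.5–47 and 40–47 Hz interpreted as constraints
  on the bifrequency sum f₁+f₂, the reading used in the original
  SynchFastSlow construction; the magnitude (not squared magnitude or
  real part) of the averaged bispectrum is summed.  Since the denominator
  region is a subset of the numerator region, SFS ≥ 0 always; a
  denominator at the floor returns a capped value (12) with a flag.

All four features are invariant under amplitude scaling (log-ratios
cancel, SEF is a quantile, PE is ordinal), so electrode gain does not
matter.

## Fusion models

The network is fixed at 4-4-7-1 — four inputs, hidden layers of four and
seven logistic units, one logistic output scaled to 0–100.  The classic
hidden-node count heuristic d = a + b + c (inputs a = 4, outputs b = 1,
constant c ∈ 1..10) brackets the 7-unit layer; the architecture itself is
not searched at runtime.  Inputs are z-scored with training statistics;
targets are scaled to [0, 1].

Training is full-batch gradient descent with momentum 0.9, learning rate
0.2, at most 5000 epochs, early stopping when a 10% seeded validation
split fails to improve for 100 epochs, and the best-validation weights
kept.  The learning rate was chosen by a coarse sweep (0.01–0.2): below
~0.05 the network can sit on the initial logistic plateau long enough
that patience fires before any progress.  Because a few percent of
random initializations stall on that plateau at any rate, training runs
from 3 seeded initializations and keeps the best validation loss; the
whole procedure is deterministic given the seed.  Weights initialize
uniform ± 1/√fan-in.

The baseline is a linear ε-insensitive SVR (½‖w‖² + C Σ(ξ⁻+ξ⁺), C = 10,
ε = 2 index units) solved by libsvm via scikit-learn, with the primal
weights recovered from the dual coefficients (w = Σ βₙxₙ) so the stored
model is a plain linear form.  Both models clip predictions to [0, 100]
and serialize to JSON.

The model is trained as a regressor and states are derived from its
continuous output afterwards; the alternative (training a 4-class
classifier) would discard the reference's within-state information.

## Evaluation

States follow the half-open-downward convention: awake [80, 100],
light [60, 80), general [40, 60), deep [0, 40) — so an index of exactly
80 is awake and exactly 40 is general.  The convention at the boundaries
is arbitrary but fixed and documented; changing it moves only exact
boundary values.

Per-state sensitivity is Nᵢ,detected/Nᵢ,total; a state absent from the
reference is reported as missing, not 0 (the ratio is undefined).
Accuracy is trace/total and equals the totals-weighted mean of
sensitivities identically.  LOOCV leaves one subject out per fold and
pools minutes across folds before computing any metric (micro-averaging)
— on unbalanced cohorts this differs from averaging per-fold metrics,
and the pooled convention is asserted by test.  Bland–Altman reports
mean difference and bias ± 1.96·SD (sample SD) limits.  The ablation
harness reruns LOOCV for all 15 nonempty feature subsets, shrinking the
input layer to the subset size while keeping the 4-7 hidden topology.

## Desk-scale experiment sizes

The synthetic experiments are sized to run in minutes on one CPU while
keeping the statistics meaningful: the end-to-end cohort uses 8 subjects
of ~25 minutes each through the full cleaning chain; the model-recovery
experiment uses 16 subjects with targets equal to a fixed logistic map
of the four features plus N(0, 3) noise; the ablation cohort draws 8
subjects × 60 minutes directly in feature space with four independent,
equally weighted features; the permutation null shuffles targets within
subjects 20 times on a cohort constructed with balanced state priors,
where any target-independent predictor's expected accuracy is exactly
Σ pᵢ² = 0.25.

These runs demonstrate that the implementation recovers known mappings,
detects constructed coupling, and behaves correctly under its own nulls.
They deliberately say nothing about clinical discrimination: synthetic
states are cleanly separated in feature space, so cohort accuracies here
sit far above anything attainable on real patients, where deep-state
minutes are scarce and feature distributions overlap.

## Known limitations

* Single-channel only; no reference-channel (EOG-lead) regression or ICA.
* The inverse filter assumes one global AR model per record;
  slowly varying dynamics are handled only through the robust threshold.
* The permutation-entropy window count fixes the per-minute convention
  (6 × 10 s); other windowings are configuration, not defaults.
* The SFS cap for empty denominators is arbitrary (12); flagged minutes
  should be excluded from training, and degenerate-flagged minutes are.
* EDF support targets single-channel continuous recordings; EDF+ with
  multiple signals is read by selecting the first channel only.
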