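# Methods

## Problem and pipeline

The package classifies single-channel auscultation recordings — heart sounds
(phonocardiograms) and lung sounds — as normal or abnormal. The classification
unit is a short frame, not the whole recording: a recording is cut into
overlapping fixed-length frames, each frame is denoised by subtracting its
dominant principal components, summarized by 27 features, classified by a
tree ensemble, and the recording's final call is made by voting over its
frames. A separate analysis toolkit quantifies the two-microphone
noise-subtraction front end of an electronic stethoscope.

## Band filtering

Heart sounds are low-passed at 400 Hz, lung sounds band-passed 100–2000 Hz
(the clinically relevant bands a stethoscope's analog front end would
implement). Digitally these are 4th-order Butterworth designs applied
forward–backward (`sosfiltfilt`), i.e. zero-phase: transient timing of S1/S2
and crackles is preserved, at the cost of doubling the effective order. The
preconditions (rate > 800 Hz for heart, > 4000 Hz for lung) keep the band
edges below Nyquist.

## Segmentation

Frame grids: 1 / 1.5 / 2 s for heart, 3 / 4 / 5 s for lung; overlaps 0%,
20%, 50%. For signal length `L`, frame `F`, hop `H = F(1−overlap)`, the
frame count is `⌊(L−F)/H⌋ + 1`; trailing samples that do not fill a frame
are dropped (padding would dilute frame statistics with synthetic silence).
Frame start times are quantized to whole samples by round-half-even of
`k·H·rate`, which is exact on the grid rates used here. A recording
producing fewer than two frames is excluded from all counts — recorded in
the output rather than silently dropped, so sample accounting stays
auditable.

## PCA-residual denoising

A frame is reshaped into an `n_subwindows × w` matrix of consecutive equal
sub-windows (default 20 rows; for a 2 s heart frame each row is 100 ms, well
below one cardiac cycle, so the repeating template aligns across rows).
Columns are mean-centered and an SVD taken; the smallest leading set of
components whose cumulative explained variance reaches the contribution
threshold (default 0.95, valid range 0.85–0.95) is reconstructed and
subtracted. Any trailing remainder that does not fill a sub-window passes
through unmodified (frame lengths on the standard grids divide evenly, so
this path is exercised only off-grid).

How a 1-D frame becomes a PCA-able matrix is a genuine design choice: the
consecutive sub-window embedding is the simplest whose low-rank part
captures a repeating heartbeat/breath template while a same-length residual
signal falls out positionally. The alternative — PCA across the frames of
one recording, frames as observations — is plausible but couples frames and
complicates per-frame bookkeeping; the embedding is isolated in one module
so it can be swapped.

Degenerate rule: an (effectively) zero-variance frame yields an all-zero
residual with `removed_fraction = 1` and zero components removed. The
degeneracy test is relative (`total variance ≤ 1e−20 × frame energy`)
because an exactly constant frame still centers to O(1e−17) rounding noise.

Note the removal is of *within-frame variance across sub-windows*. For heart
frames the S1/S2 template is low-rank and dominant, so murmur bursts survive
in the residual. For lung frames the breath sound itself is broadband noise
with no low-rank structure, so a 95% cut removes most of everything,
including part of a wheeze tone — one reason the lung task scores lower than
the heart task here, as it does on real corpora.

## Features (27 per frame)

* **Statistical (11)** — mean; sample (n−1) standard deviation; mean absolute
  deviation; median; Q1; Q3 (linear interpolation on sorted data); IQR;
  adjusted Fisher–Pearson skewness; Pearson kurtosis (normal = 3); Shannon
  entropy in bits of a 16-equal-width-bin amplitude histogram over
  [min, max]; spectral entropy of the periodogram normalized by log2(#bins)
  to [0, 1] (frame-length invariant: ≈ 0 for a pure tone, → 1 for white
  noise). Zero-variance frames set entropy, skewness and kurtosis to 0.
* **Cepstral (13)** — pre-emphasis 0.97; 25 ms Hamming sub-windows at 10 ms
  hop; power spectrum (FFT zero-padded to ≥ 512 points so the 40 Mel filters
  are resolvable at a 2 kHz rate); 40 triangular Mel filters spanning
  0–rate/2 on the scale `2595·log10(1 + f/700)`; log energies floored at
  1e−10; orthonormal DCT-II; coefficients 1–12 averaged across sub-windows;
  the 13th value is the log total frame energy (same floor). Averaging
  short-time MFCCs to one vector per frame is the standard frame-level
  summary when one vector per frame is required.
* **Power spectrum (3)** — full-frame periodogram peak power, its frequency,
  and its share of total spectral power.

All 27 values are finite for every frame the generator can produce (fuzzed
in the test suite).

## Ensemble classifiers

Five methods share one train/predict contract (labels 0 = normal,
1 = abnormal; internal ±1 coding; decision `score > 0`):

* bagging — scikit-learn `BaggingClassifier` over decision trees;
* AdaBoost — discrete AdaBoost, `alpha = ½·ln((1−err)/err)`, exponential
  reweighting; rounds stop at `err ≥ 0.5`; a zero-error learner gets a
  capped vote weight and ends the loop;
* GentleBoost — per round, a regression tree fit to the ±1 labels under the
  current exponential weights (Newton step);
* LogitBoost — weighted least squares on the clipped working responses
  `z = (y* − p)/(p(1−p))`, `F ← F + ½·lr·h`, `p = σ(2F)`;
* RUSBoost — AdaBoost whose per-round learner trains on a class-balanced
  random undersample (all minority + equally many majority samples).

Depth-1 base learners in the AdaBoost family are exhaustive
minimum-weighted-error stumps (vectorized by prefix sums over sorted feature
values, ties broken toward the lowest feature index then smallest
threshold); deeper learners are scikit-learn trees fit with sample weights.
An impurity-driven depth-1 tree does not generally minimize weighted 0-1
error, which the stump-optimality property requires.

**Model selection.** `select_model` runs 5 trials; each trial draws one of
the five methods uniformly at random and tunes `(n_learners, tree depth,
learning rate)` by Bayesian optimization — Matern-5/2 Gaussian-process
surrogate, expected-improvement acquisition over random candidate draws,
objective = mean stratified 3-fold accuracy on the training frames. Default
budget: 20 evaluations over n_learners ∈ [50, 500], depth ∈ [1, 4], learning
rate ∈ [0.01, 1] (log scale). The best trial's settings are refit on all
training data. Accuracy (not F1) is the objective and 20 the budget; both
are configurable since neither is canonical.

## Voting and evaluation

A recording is abnormal when its abnormal-frame fraction **strictly
exceeds** the voting threshold (a tie votes normal); thresholds sweep
5%…95% in 5% steps (19 values). Metrics per threshold: accuracy,
specificity, sensitivity, precision, F1 (F1 = 0 when Se + precision = 0;
any zero denominator maps to 0 with a logged warning). Evaluation is
stratified k-fold at the sample level — frames of one recording never
straddle folds — with 5 folds for heart and 3 for lung; stratification is
used because heavily imbalanced corpora make unstratified small-k splits
fragile. The reported metrics are unweighted means of per-fold metrics, not
pooled counts. If a split leaves a fold single-class the split is reseeded
(logged) up to five times before erroring.

## Synthetic data generator

The generator emulates the statistical structure the classifier relies on,
not physiologic waveform detail:

* **Heart** (default 2000 Hz, 10 s): `⌊bpm·duration/60⌋` cardiac cycles at
  50–80 bpm; S1 = Gaussian-windowed 40 Hz tone (60 ms width), S2 = 60 Hz
  tone (40 ms) at systolic fraction 0.35 of the cycle; abnormal recordings
  add band-limited murmur noise (default band 150–400 Hz, relative amplitude
  0.5) windowed into systole; a 0.5% sensor-noise floor; peak-normalized to
  0.95. The periodic S1/S2 template dominates total energy, which is the
  dominance the PCA step assumes.
* **Lung** (default 8000 Hz, 15 s — long enough that 5 s frames at 50%
  overlap give ≥ 2 frames): one raised-cosine breath envelope per cycle at
  12–20 breaths/min modulating 100–1000 Hz band noise; wheeze = tone
  (default amplitude 0.4, frequency drawn 200–800 Hz) during the expiratory
  half; crackles = 4 ms damped 650 Hz transients at `⌊rate·duration⌋`
  events; abnormal iff wheeze or crackles present.
* **Noise mixtures**: ward-construction and airport noise stand-ins are
  white noise band-passed to 150–450 Hz and 100–600 Hz (the measured bands
  of those sources); the coupled copy reaching the primary microphone is
  scaled so the clean-to-noise power ratio equals the requested SNR; the
  reference channel carries the pre-coupling process. Coupling = gain,
  integer-sample delay, and a multiplicative frequency shift implemented by
  Fourier time-stretching — with identity coupling, `primary − reference`
  recovers the clean signal exactly; a 1.08 shift leaves a substantial
  residual, reproducing the media-dependent imperfect cancellation seen with
  real stethoscope heads.

What the generator does *not* model: disease subtypes, heart-rate
variability, respiratory splitting of S2, recording artifacts, or realistic
murmur spectra. Passing tests therefore demonstrate that the pipeline
recovers the intended signal structure under controlled conditions, not
clinical-grade performance on real corpora.

## Problem sizes and numerical choices

End-to-end experiments in the tests and the acceptance script use 30 normal
+ 30 abnormal recordings per corpus and run model selection at 5 trials ×
6 BO evaluations over n_learners ∈ [20, 150] — small enough for interactive
runs while keeping every pipeline stage (including randomized trial
selection) exercised; the library defaults keep the larger 20-evaluation
budget. On these corpora the heart task is essentially solvable (accuracy
≈ 1.0 at the 20% voting threshold) and the lung task materially harder
(≈ 0.65–0.75), mirroring the heart/lung gap reported on clinical corpora.

Other numerics: WAV output is 16-bit PCM with symmetric 1/32768 full-scale
(round-trip error ≤ 1 LSB); resampling is polyphase rational; spectrum
summaries use an amplitude-corrected Hann window by default (boxcar
available where exact Parseval bookkeeping is wanted); band summaries report
contiguous runs at ≥ 10% of the spectrum peak, a cut level chosen for
readable band tables; near-perfect cancellation in the noise report floors
the post-subtraction peak at 1e−9 of the pre-subtraction peak so the dB
ratio stays finite.

## Known limitations

* One frame-length inconsistency in common descriptions of this pipeline is
  resolved in favor of true sample counts: a 2 s frame at 2000 Hz is 4000
  points, and all bookkeeping uses actual frame lengths.
* MFCCs are computed on the PCA residual (the difference signal), following
  the design that features describe the residual; computing them on raw
  frames is a one-line change but not exposed as an option.
* 24-bit PCM WAV input is not supported (scipy's reader limitation);
  8/16/32-bit integer and float WAVs are.
* The Bayesian optimizer is a light GP-EI loop over random candidates, not a
  general-purpose optimizer; its purpose is faithful reproduction of the
  randomized 5-trial selection protocol at small budgets.
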