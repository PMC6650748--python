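# Methods

This note documents the models, numerical choices and known limitations of
`sounddissim`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic-data defaults do and do not
emulate.

## Stimulus synthesis

The synthetic set reproduces the *structure* of a three-category natural
sound study — 12 vocal, 12 instrument and 12 environmental items, 250 ms
each, with F0 matched across categories via equal-tempered notes — not the
perceptual realism of its recordings.

* **Vowels** are a jittered harmonic source (per-harmonic rolloff k^-tilt,
  0.2% low-passed F0 jitter) filtered through a Klatt-style two-resonator
  cascade with canonical formants (/ɑ/: F1 710, F2 1100 Hz; /i/: F1 280,
  F2 2250 Hz).  Speakers differ by a formant scale factor (vocal-tract
  length analog, 0.96–1.20) and glottal tilt (1.8–2.4).
* **Default F0 table.**  Published materials give the vocal F0 *range*
  (99.16–251.38 Hz) and the nine matched notes {G2, A♭2, A2, B♭2, B2, C3,
  A♭3, B♭3, B3}, but not per-speaker values.  The default table fixes 12
  F0s whose nearest notes are exactly that nine-note set and whose extremes
  are the published range endpoints; male speakers occupy the low octave,
  female speakers the high one.  Sampling F0 uniformly in the range was
  rejected because it would not reproduce the matched-note set.
* **Instruments** are deterministic additive tones: harmonic k has
  amplitude exp(−(k−1)/brightness); the envelope rises linearly over the
  attack (2–80 ms across the 12 presets) and either sustains (bowed, wind,
  brass) or decays exponentially (plucked, struck).  Families follow the
  usual orchestral taxonomy (plucked strings, bowed strings, woodwinds,
  brass, percussion).
* **Environmental recipes** follow the everyday-sound excitation-media
  taxonomy: impact = decaying broadband burst; air = low-passed sustained
  noise; liquid = sparse decaying downward chirps over a quiet noise bed;
  deformation = gated noise crackle; mechanical = noise amplitude-modulated
  at 25/50 Hz; movement = band-passed noise under a slow low-passed random
  amplitude walk.  Sparse-event recipes force one event inside the first
  10–20 ms so every token retains a full 250 ms after onset detection.
* Synthesis is 44.1 kHz, 300 ms pre-trim (leaving material for onset
  trimming), bit-reproducible given (config, seed).

What the set does *not* emulate: consonant transitions, stereo imaging,
room acoustics, recording noise, or instrument-specific spectral detail.
Passing tests therefore establish that the *analysis machinery* behaves
correctly on data with the right category-level acoustic contrasts, not
that it would reach identical conclusions on any particular recorded set.

## Preprocessing

Onset = first sample whose high-pass-filtered |amplitude| *strictly*
exceeds 10% of the filtered maximum.  The filter is a 2nd-order Butterworth
at 20 Hz applied forward–backward (zero phase, 4th-order magnitude) and is
used **only** for onset detection; output samples come from the unfiltered
waveform.  Trim to 250 ms from onset, 5-ms raised-cosine ramps, then RMS
normalization to 0.05 full scale (ramp-then-normalize; the target level is
a free choice since every downstream feature is either level-invariant or
compared within-set).  Stereo input keeps channel 0 (left).

## Features

* **Cochleagram**: 77 channels, center frequencies equally spaced on the
  Glasberg–Moore ERB-rate scale from 30 Hz to 16 kHz.  Each channel is a
  4th-order gammatone realized as a cascade of four identical complex
  one-pole filters (pole exp((−2πb + 2πi·cf)/sr), b = 1.019·ERB(cf)); this
  form is numerically stable at every center frequency, and the complex
  output magnitude directly gives the channel envelope.  Channel gains are
  equalized by 1/√bandwidth (referenced to 1 kHz) so white noise produces a
  flat channel-energy profile — without this the wider high-frequency
  channels collect more noise energy and bias the flatness statistic.
  Envelopes are averaged in non-overlapping frames at 200 Hz (≥ 50 frames
  per 250-ms clip).
* **Spectral centroid/flatness** per frame over channels; flatness uses a
  1e-12 floor before the geometric mean.  All-zero frames yield NaN and are
  excluded from medians/IQRs.  **Spectral variability** is 1 − Pearson r of
  successive channel spectra; zero-variance steps are skipped.
* **YIN**: 25-ms integration window, 5-ms hop, cumulative-mean-normalized
  difference function, dip threshold 0.1, parabolic interpolation; the dip
  depth d′(τ*) ∈ [0,1] is the frame's aperiodicity.  The search floor is
  80 Hz: the window must span two periods of the lowest search frequency,
  and 2/80 Hz = 25 ms exactly, while still clearing the 99–251 Hz vocal
  range with margin.  All frames enter the summaries (environmental sounds
  have no voiced subset to restrict to); this is what makes the F0 IQR of
  noise tokens large by construction.
* **Temporal features**: RMS envelope in 10-ms frames, 2.5-ms hop; attack
  endpoints are the *first crossings* of 10% and 90% of the envelope
  maximum (the standard effort-threshold convention); log-attack-time is
  log10 of their difference, floored at one hop.
* **Modulation power spectrum**: the printed modulation-axis maxima
  (47.92 Hz temporal, 31.24 cyc/kHz spectral) fix the spectrogram sampling
  — hop = 1/(2·47.92) s and frequency-bin spacing = 1/(2·0.03124) Hz — but
  not the analysis window; the Gaussian window σ is set equal to the hop
  (window length ≈ 6σ), recorded here as the package's choice.  The
  log-magnitude spectrogram is clipped to 50 dB below its maximum before
  the 2-D FFT; the spectral-modulation axis is folded to ≥ 0 (Hermitian
  symmetry).  As a distance representation the MPS is flattened on a dB
  scale.

## Dissimilarity and simulated behavior

Acoustic distances: |Δ| for scalars, Euclidean for vectors.  RSA operates
on unordered-pair vectors (630 entries for 36 items) after symmetrizing the
behavioral matrix; an ordered-pair mode (1260 entries) is available since
the published analyses do not state which was used.  Instrument features
default to the E3 rendering.

The **rater model** maps a weighted sum of z-scored feature distances
through a logistic squash to (1, 9): rating = 1 + 8/(1 + e^(−1.5z)), plus a
per-participant criterion shift (sd 0.5) and per-trial noise (sd 1.0),
rounded and clipped to 1..9.  Default weights put aperiodicity first (1.0)
with spectral variability, spectral centroid, cochleagram envelope,
temporal centroid, flatness and attack contributing (0.2–0.35).  The weight
hierarchy deliberately gives the top feature a clear margin over its
collinear competitors so the generating structure remains identifiable in
recovery analyses; near-equal weights on highly correlated features would
make "which feature drove the ratings" ill-posed for any method.
"Noise-free" in recovery contexts means zero *response* noise; the
between-participant criterion diversity is retained, which also
de-quantizes the group average (integer ratings from identical raters would
cap the achievable τ-b through ties alone).

The **identifier model** draws responses with weight exp(−d/temperature) +
self-bias on the correct item, where d is the weighted feature distance
rescaled so the off-diagonal minimum stays strictly positive (the item
itself, at d = 0, always remains the closest option).  Confusions
concentrate within subcategories because feature distances are smallest
there by construction.  Identification runs in 10 blocks; the default
pipeline uses E3-rendering features for all blocks (the same convention the
feature analyses use), with note-specific distance tables accepted
explicitly when note variability should enter the confusions.

Counterbalancing: unordered pairs alternate orders between two
complementary 630-trial lists; participants alternate lists; each list
splits into 3 blocks of 210.

## Statistics

* **Kendall τ** is tie-corrected τ-b throughout (scipy for single values;
  a vectorized pairwise-sign batch path for permutation nulls on short
  vectors, an O(m log m) per-row path for long ones — both validated
  against an O(m²) pair-count oracle).
* **Semi-partial τ**: ranks of the target feature's distances are
  residualized on the ranks of the other features by least squares, and the
  behavior is correlated with the residual.  Residualizing the *predictor*
  matches the "holding the other features constant, for each feature"
  reading; a rank-based residualization matches the rank-ordered base
  statistic.  This is one admissible formulation — recursive partial-τ
  identities exist but are not implemented as the default.
* **Permutation inference**: the behavior vector is permuted; r counts null
  statistics ≥ the observed one; p = (r+1)/(n+1), one-sided (large positive
  τ), n = 10,000 by default.  Each (subset, feature, statistic) gets its
  own seed stream derived from the master seed.
* **FDR** is Benjamini–Hochberg, applied within each subset × statistic
  family (whether correction spanned subsets jointly is unstated in the
  source analyses; within-subset is the package's choice).
* F0 features enter only where F0 was free to vary: median + IQR in
  vocal–vocal, IQR in vocal–instrument, neither elsewhere (including the
  overall analysis, where F0 was deliberately equated across categories).

## Ordinal MDS

Nonmetric SMACOF: disparities by isotonic regression of configuration
distances on dissimilarity ranks (primary/untie approach to ties),
rescaled to the current distance norm; Guttman transform; Kruskal stress-1;
tol 1e-6 relative stress change, max 1000 iterations.  Initialization is
classical Torgerson scaling plus (n_starts − 1) random starts (default 8);
best stress wins, with ties broken toward the Torgerson start.  The final
configuration is centered, rotated to principal axes, and sign-fixed
(largest-|coordinate| positive per axis); `dimension_feature_correlations`
additionally re-orients each axis so its dominant feature correlates
positively.  The rating-matrix diagonal is defined as the scale minimum
(identical pairs were never presented); the fit itself uses off-diagonal
pairs.

**Known limitation**: under weak monotonicity, data containing an "outlier"
item whose dissimilarities all exceed the remaining pairs admit a perfect
degenerate solution (everything else collapsed to a point) with stress 0 in
any dimensionality.  This is a property of ordinal stress itself, not of
the optimizer; well-spread configurations do not exhibit it, and the test
fixtures use such configurations.

## Behavioral analyses

Wilcoxon signed-rank tests against chance use scipy's automatic
exact/approximate switching (exact for small n without ties), one-tailed
(greater), zero differences dropped; BH-FDR across items.  Subcategory
recoding counts any response in the stimulus's subcategory as correct, so
recoded accuracy is bounded below by raw accuracy cell-wise.  The
confusion ↔ rating comparison averages both matrices across their
diagonals, includes the diagonal in full mode (ratings diagonal = scale
minimum), and in restricted mode keeps only off-diagonal cells with at
least one confusion.  Split-half reliability averages 100 random
participant halves (Pearson over ordered-pair means, Spearman–Brown
adjusted); the published analysis names only the adjustment, not the split
scheme, so averaged random splits are the package's choice.

## Problem sizes

Default analyses use the full 36-item design (630 unordered pairs).  The
test suite and acceptance script run permutation inference at n = 99–999
for calibration experiments and n = 10,000 only where a single report is
needed; recovery experiments use 20 independently seeded stimulus sets with
50 simulated raters each, and the type-I calibration uses 2000 null
datasets of 20 pairs at 999 permutations.  These sizes were chosen to keep
a complete verification run in minutes on one CPU while leaving every
statistical conclusion comfortably powered.
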