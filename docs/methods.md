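# Methods

This document describes the model underlying `musetrf`, the default
parameter choices and why they were made, what the synthetic data generator
does and does not emulate, and the main numerical and design decisions.

## 1. Overview

The package implements a complete analysis chain for testing whether a
listener's brain encodes *musical expectations* — and whether those
expectations are driven by rhythm, by melody, or by both:

1. **Information dynamics** (`musetrf.ppm`, `musetrf.infodyn`): a
   variable-order Markov model assigns every note a *surprise* (negative log
   probability) and an *entropy* (uncertainty of the prediction before the
   note), separately for the pitch and the timing stream.
2. **Continuous feature regressors** (`musetrf.features`): the note-level
   quantities are expanded into impulse trains aligned to note onsets at the
   EEG sampling rate, alongside low-level covariates (onset, inter-onset
   interval, interval size, optional acoustic envelope/flux).
3. **Encoding model** (`musetrf.trf`): lagged ridge regression (a temporal
   response function, TRF) maps the regressors to EEG, evaluated by
   leave-one-melody-out cross-validation.
4. **Variance partitioning** (`musetrf.vp`): the unique contribution of a
   feature group is the drop in cross-validated accuracy when that group's
   impulse amplitudes are shuffled across note onsets, with mixed-model
   inference over subjects and melodies.
5. **Event-related potentials** (`musetrf.erp`): notes are split into
   high/low-surprise quantiles within each melody and the evoked-response
   difference is tested with a spatiotemporal cluster permutation test.
6. **Synthetic ground truth** (`musetrf.stimgen`, `musetrf.simulate`):
   a melody generator and a forward EEG generator with known kernels allow
   every stage to be validated against planted effects.

## 2. Sequence model

### 2.1 Prediction by partial matching

`musetrf.ppm` implements PPM with escape method C and *interpolated*
blending.  For a context of length *k* the predictive probability of symbol
*s* is computed by the recursion

    p_k(s) = c_k(s) / (n_k + t_k)  +  t_k / (n_k + t_k) · p_{k-1}(s)

where `c_k(s)` is the count of *s* after that context, `n_k` the total count
and `t_k` the number of distinct continuations.  The recursion bottoms out at
order −1 with the uniform distribution over the alphabet, so probabilities
are always strictly positive and sum to one.  Contexts with no observations
are transparently skipped.  The implementation stores counts in a trie and is
verified in the test suite against an independent brute-force implementation
of the same recursion, exhaustively over all short sequences on small
alphabets.

Maximum order defaults to **10**: melodic dependencies beyond ten notes add
essentially nothing on corpora of this size, and the trie stays small.

### 2.2 Viewpoints

Two viewpoints are modelled independently:

- **cpitch** — the chromatic MIDI pitch, defined from the first note.
- **ioi_ratio** — the ratio of consecutive inter-onset intervals, defined
  from the third note and rounded to 6 decimals so grid-derived ratios
  compare equal under floating point.

Surprise and entropy of the two viewpoints give the four information
regressors: pitch surprise `Sp`, pitch entropy `Ep`, timing surprise `St`,
timing entropy `Et`.

### 2.3 Short- and long-term models

Each melody is scored under a combination of a short-term model (STM),
trained online on the unfolding melody only, and a long-term model (LTM),
pre-trained on the other melodies of the corpus (cross-validated over
`folds = 10` resampling folds so no melody is scored by a model that saw
it).  By default the LTM also keeps learning while the melody unfolds
(`ltm_online = True`, the "both+" configuration); `ltm_online = False` gives
the frozen-LTM variant.

STM and LTM distributions are combined by an entropy-weighted geometric
mean: each model's weight is proportional to `(H / log2 |A|)^(-bias)` with
`bias = 2`, so the more confident model dominates.  Entropies are floored at
`1e-6` to keep weights finite for deterministic distributions.

The first note of a melody has an empty context in both models, so its
surprise is exactly `log2 |alphabet|` — a property the tests assert.

## 3. Stimulus generation

`generate_corpus` draws melodies from first-order Markov chains over a
15-pitch alphabet and an 8-value IOI-ratio alphabet.  Transition matrices are
sharpened by a `temperature` parameter (default 0.3; lower = more
predictable) and renormalised so all IOIs stay on a sixteenth-note grid.

`shuffle_melody` builds the *shuffled control* for a melody: the pitch
sequence is randomly permuted (identical pitch multiset, destroyed melodic
structure) and the IOIs are redrawn from a Gaussian with matched mean
(rejection-sampled into the valid range, then snapped to the sixteenth grid),
destroying the rhythmic structure while preserving overall note density.
These controls should carry systematically higher surprise than their
structured sources — a property verified in the tests.

## 4. Feature regressors

Regressors are impulse trains at 100 Hz: zero everywhere except at the
sample nearest each note onset, where the amplitude is the note's value of
the feature (1 for `onset`, the preceding IOI in ms for `ioi`, absolute
pitch interval in semitones for `ipi`, and the information estimates for
`Sp`/`St`/`Ep`/`Et`).  Undefined values (first notes, NaN estimates) become
zero-amplitude impulses so they simply do not contribute.  Optional acoustic
regressors (broadband envelope, spectral flux from a 32-band filterbank of a
rendered tone audio signal) capture low-level acoustic confounds.
`FeatureMatrix.normalize()` scales each column to unit RMS so ridge
penalisation treats features comparably.

## 5. Synthetic EEG

`generate_eeg` plants a known forward model:

- **Kernels.** Each active feature gets a rank-1 spatiotemporal kernel: a
  lag curve made of signed gamma bumps at roughly 80/150/230/310 ms (an
  N1–P1–N2–P2 morphology) times a Gaussian scalp topography on a hemispheric
  electrode layout.
- **Subject variability.** Per subject, kernel latencies are jittered
  (SD 10 ms) and gains drawn log-normally (SD 0.2), so group analyses face
  realistic between-subject variance.
- **Noise.** Spatially correlated 1/f noise is added and rescaled *after
  filtering* so the realized 1–30 Hz SNR is exact per subject × melody.
  This makes the SNR parameter interpretable and reproducible.
- **Condition gains.** `condition_gains` multiplies a feature's kernel per
  stimulus condition — e.g. setting the timing-surprise gain to 0 for
  shuffled melodies plants exactly the asymmetry the pipeline is designed to
  detect (rhythmic predictions present for structured stimuli, absent for
  shuffled ones).

The generator emulates: evoked responses linear in the regressors, subject
variability, condition-specific encoding, realistic noise spectra and
spatial correlation.  It does **not** emulate: non-linear or adaptive
responses, oscillatory entrainment, artefacts (blinks, movement), electrode
drift, or volume-conduction from discrete dipoles — topographies are
idealised Gaussians.

## 6. Preprocessing

`preprocess_recording` applies, in order: zero-phase band-pass (3rd-order
Butterworth, 1–30 Hz, `sosfiltfilt`), polyphase resampling to 100 Hz,
iterative bad-channel detection (robust z > 2.75 on per-segment mean, SD and
peak-to-peak, two passes), re-referencing to the average of F9/F10/P9/P10/Iz
(flagged reference electrodes are dropped from the average; common average
is the fallback when those labels are absent), and interpolation of bad
channels by the mean of neighbours within 18 mm.

Neighbour-mean interpolation is exact for locally linear fields only when
the neighbourhood is symmetric around the interpolated electrode.  On the
hemispheric layout the neighbour centroid is offset from the electrode, so a
bias proportional to the local field gradient remains; the tests quantify
this on a regular planar grid (where the error is far below one
gradient-step) and bound it loosely on the hemisphere.

## 7. TRF encoding model

The design matrix contains one column per feature × lag for lags −50…400 ms
at 100 Hz (46 lags); negative lags let the model absorb slow anticipatory
components and provide a sanity window.  Each melody is treated as its own
epoch: design and EEG are mean-centred *per melody* before pooling, so
melody-specific offsets cannot leak across folds.

Accuracy is leave-one-melody-out: for each held-out melody the model is
trained on the remaining melodies and its prediction is correlated, per
channel, with the *super subject* (the group-mean EEG), following the logic
that at low per-subject SNR the single-subject recording is too noisy to be
a useful evaluation target itself.
The ridge parameter is selected per subject from a decade grid
10⁻⁴…10⁸ by mean cross-validated accuracy.

Numerically, cross-validation over the λ grid is batched: the pooled Gram
matrix is eigendecomposed once per fold, and correlations for all λ are
obtained with `einsum` — mathematically identical to solving each ridge
problem separately (asserted against a naive loop in the tests) but an order
of magnitude faster.

## 8. Variance partitioning

The unique contribution of a feature group is `Δr = r_full − r_reduced`,
where the reduced model *shuffles the impulse amplitudes of that group
across note onsets* (preserving onset times, amplitude marginals and all
other regressors).  Shuffling, rather than deleting, keeps the design
dimensionality and collinearity structure fixed.  Five standard reduced
models are defined: `highlevel` (all four information features), `timing`
(`St`+`Et`), `pitch` (`Sp`+`Ep`), `ioi`, `ipi`.

Statistics are computed on Δr averaged over each subject's ROI — the top
25 % of channels by full-model accuracy — within each condition:

- one-sided Wilcoxon signed-rank tests of Δr > 0 per cell,
- a linear mixed model (`statsmodels MixedLM`, crossed random intercepts
  for subject and melody via variance components, ML fit) with sequential
  likelihood-ratio χ² tests for condition, model, and their interaction,
- Tukey-corrected pairwise contrasts via the studentized range.

## 9. ERP analysis

Notes are epoched −100…+500 ms, baseline-corrected on −50…0 ms, and trials
exceeding 2.5 robust SDs (two iterations) are rejected.  Within each melody,
the top and bottom 20 % of notes by surprise form the high/low conditions;
quantiles are within-melody so the contrast is not confounded by
melody-level differences, and ties are resolved by stable sort for
determinism.  Subject-level difference waves (trimmed to −50…400 ms, the TRF
window) enter a paired sign-flip spatiotemporal cluster permutation test:
samples with |t| above the two-sided α = 0.025 threshold per polarity are
clustered over channel adjacency (30 mm) and time, clusters need ≥ 3
distinct channels, the null is the maximum |cluster mass| over sign flips,
and p-values use the add-one rule.  The observed cluster masses are verified
in the tests against the reference implementation in `mne`.

## 10. Determinism

Every random decision is derived from a single integer seed: child seeds are
produced by seeding a generator with `[seed, crc32(tag)]` for a descriptive
string tag, keeping all derived seeds below 2³¹ and independent of call
order.  Output files avoid timestamps, fix float formatting (`%.10g`), sort
JSON keys, and write figures as SVG with the date metadata stripped, so a
rerun of the full pipeline is byte-identical — a property asserted by the
tests.

## 11. Default problem sizes

The package's own default study — chosen to exercise every code path at
realistic yet tractable scale — is 10 structured melodies of 60 notes plus
4 shuffled controls, 20 subjects, 64 channels, SNR 1.  Validation problems
in the tests are sized for statistical meaningfulness: kernel recovery at
SNR 1 uses ~5 minutes of signal (10 melodies × 80 notes), the planted
condition × model interaction is detected across repeated simulated studies
of 30 subjects, and cluster-test calibration uses hundreds of null
simulations.

## 12. Limitations

- PPM is the only sequence model; no comparison against RNN/transformer
  surprise estimates.
- The melody generator is first-order Markov — long-range musical form
  (phrases, cadences) is absent, so information estimates on synthetic
  corpora are easier than on real music.
- The forward model is linear and rank-1 per feature; real evoked responses
  mix sources and adapt over time.
- Neighbour-mean interpolation is biased on curved montages (see §6);
  spline or spherical-harmonic interpolation would remove this at the cost
  of a heavier dependency.
- The super-subject evaluation target means per-subject accuracies are not
  independent; the mixed model treats subjects as exchangeable given the
  random intercepts, which is an approximation.
- MIDI support covers single-track monophonic note streams (the stimulus
  format), not general polyphonic scores.
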