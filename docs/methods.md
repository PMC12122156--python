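# Methods

`voicedep` implements a voice-biomarker depression-screening pipeline and a
synthetic clinical cohort to exercise it. Real cohorts of this kind —
outpatient voice recordings paired with a validated depression label
(questionnaire cut-off), a 1–10 SUDs self-report and a somatic-symptom
(PHQ-15) score — are private; the package therefore ships a generator whose
defaults encode the published study conditions, and every downstream stage
is tested against it.

## Synthetic cohort model

**Metadata.** Each patient has a latent severity `s ~ N(0, 1)`. The binary
depression label is a quantile cut on severity so the cohort's depressed
fraction equals the requested prevalence to within one patient (defaults:
143 patients, 86% women, prevalence 0.625; the women-only arm uses 0.642).
SUDs is `clip(round(5 + 4.5 (s + ε)), 1, 10)` with `ε ~ N(0, sd)`; the
scale and the default noise sd (0.35) were fixed once by a grid-search
oracle so that corr(SUDs, label) ≈ 0.75, the extreme-SUDs tails
(SUDs ∈ {1, 9, 10}) hold roughly 40–45% of patients at near-balanced
prevalence, and mean SUDs ≈ 5 — the structure the analysis relies on. The
heavy clipping at both ends of the 10-point scale is what produces the
large low/high tails. PHQ-15 derives from a pain latent correlated with
severity at r = 0.5, mapped affinely to 0–30.

**Waveforms.** Recordings are mono 16 kHz, duration ~ N(66.73 s, 17.819 s)
truncated at 15 s. Voiced vowel-like segments (1.5–3.5 s) alternate with
silent pauses sized to a target pause fraction (default 0.30). Each voiced
segment is a glottal-pulse train — per-cycle period jitter, per-cycle
amplitude shimmer, a slow F0 wobble, plus aspiration noise at −26 dB —
filtered through a cascade of three second-order resonators with standard
vowel formant targets. Base F0 is drawn per patient from a gender band
(85–155 Hz male, 165–255 Hz female), which makes gender the dominant
acoustic factor, as observed in real cohorts.

**Depression effect and chunk correlation.** Six parameters carry the
label effect: F0 mean and F0 wobble depth down, energy down, jitter and
shimmer up, pause fraction up. A depressed patient's parameter is shifted
by `effect_size` population standard deviations (default 1.0, a strong but
plausible prosodic effect; it is the main dial the monotonicity property is
tested against). The remaining variance splits into a per-patient offset
(`sqrt(icc) · sd`) shared by all segments and per-segment noise
(`sqrt(1-icc) · sd`), giving chunk-level features an intraclass correlation
of `chunk_icc` (default 0.5).

All randomness flows from one integer seed; per-patient substreams are
keyed by a CRC32 of the patient id, so waveforms are reproducible
individually and cohorts bit-identical across runs.

**What the generator does not emulate:** phonetic content, language,
interviewer speech, device/compression effects, age or comorbidity
structure, and any nonlinear severity–acoustics relation. Passing tests
demonstrate that the pipeline recovers a known injected effect with correct
calibration under the null — not that the effect exists in real patients.

## Enhancement (log-MMSE)

Frames of 32 ms (Hann, 8 ms hop) are transformed by an internal STFT whose
overlap-add inverse reconstructs interior samples to < 1e-6 relative error.
Per-bin gains follow the log-spectral-amplitude MMSE estimator
`G = ξ/(1+ξ) · exp(E1(v)/2)`, `v = ξγ/(1+ξ)`, with the decision-directed
a-priori SNR (α = 0.98, floor −25 dB) and `E1` from `scipy.special.exp1`.
Gains are clipped to [1e-3, 1], so the enhancer never amplifies. Two
numerical choices differ from the most common textbook recipe, both because
synthetic recordings open mid-speech: the noise PSD initialises from the
lowest-energy frames (≥ 6, up to 5% of the signal) rather than the leading
frames, and the noise-tracking speech-absence test uses the Gaussian
log-likelihood-ratio statistic (mean over bins of `γξ/(1+ξ) − log(1+ξ)`
below 0.15) rather than the mean log posterior SNR, which misfires when
most bins are noise-dominated during speech. The overlap-add normaliser is
floored at 1e-3 of its maximum; otherwise the vanishing window tails would
amplify edge samples after any spectral modification.

## Segmentation and VAD

Recordings are cut into consecutive 10-s chunks; a trailing remainder of at
least 3 s is kept (the published chunk counts, ~5–6 per minute-long
recording, pin this rule down only loosely; 3 s keeps synthetic counts in
the observed 4.5–7 band). Silence is removed inside each chunk: 25 ms
frames (10 ms hop) are labelled by a linear SVM over log RMS energy,
zero-crossing rate and spectral flatness, trained once per run on frames
labelled by the generator's own speech mask (~99% frame accuracy on held
out patients); a degenerate training set triggers an energy-threshold
fallback with a warning. Chunks with under 2 s of retained speech are
dropped. Silence removal happens after slicing, so a chunk is 10 s before
removal.

## Features

A compact eGeMAPS-style set: 23 functionals over the frame-level LLDs
(F0, RMS energy, HNR, jitter, shimmer, 0–500 Hz spectral slope voiced and
unvoiced, F1–F3 frequencies, F2/F3 amplitude relative to F0, MFCC 1–4) —
the arithmetic mean and `stddevNorm` (population sd over |mean|, floored at
1e-9) per LLD, plus the voiced fraction. Numerical details that matter:

* F0: autocorrelation with unbiased lag normalisation, parabolic
  interpolation, 60–400 Hz search band, voicing threshold 0.45. Octave
  errors are suppressed by taking the shortest lag whose local maximum is
  within 10% of the frame's best peak, not the global argmax.
* HNR: `10 log10(r/(1−r))` at the pitch lag, capped at 60 dB.
* Jitter/shimmer: cycle peaks via distance-constrained peak picking inside
  voiced runs; mean absolute consecutive difference over the mean, pooled
  across runs; fewer than three usable periods → missing.
* Formants: order-18 LPC (autocorrelation method, Levinson–Durbin
  vectorised across frames; batched companion eigenvalues), roots with
  bandwidth < 400 Hz; every second voiced frame is analysed since formants
  vary slowly. Amplitudes are measured on the frame spectrum at the
  harmonic peaks nearest the formant and the fundamental, so the window
  gain cancels.
* Spectral slope: log-magnitude regressed on log2 frequency (dB/octave)
  over the band's bins, pooled separately across voiced/unvoiced frames.
* Missing values stay NaN in the table and are imputed with the
  training-fold column median at fit time, never with pooled statistics.

## Classification, voting, evaluation

The chunk classifier is a gradient-boosted tree ensemble (LightGBM) with
100 iterations, learning rate 0.05, depth 3 and balanced class weights; the
learner is pluggable behind `TrainConfig`. A patient is called positive
when at least `min(τ, r)` of their `r` chunks exceed the 0.5 probability
threshold; the cap avoids forcing patients with fewer chunks than τ
negative. Cross-validation is patient-grouped (all chunks of a patient on
one side) and label-stratified with seeded fold assignment; fold metrics
are averaged with equal weight and spread is the population sd over folds.
Patients whose chunks were all discarded by the silence filter receive a
negative call. Self-report fusion appends SUDs and/or PHQ-15 as constant
columns on a patient's chunk rows.

Lift significance uses the binomial normal approximation:
`σ = sqrt(p0(1−p0)/n_test)`, `σ' = σ/√k`, `Z = lift/σ'`, one-tailed
`p = 1 − Φ(Z)`, no continuity correction.

## Attribution

For tree ensembles, per-row log-odds attributions come from LightGBM's
exact tree-path (Shapley) decomposition, so attributions plus the base
value reproduce the raw score to machine precision; for other learners a
seeded 20-repeat permutation importance supplies global rankings only, and
the report records which method produced it. Log-odds are read through the
logistic function `1/(1+e^{−x})` (a +0.5 attribution on a neutral base is
62.2%, +1.5 is 81.76%).

## Problem sizes in the test suite

The suite regenerates everything programmatically: a 200-patient
effect-size-1 women's cohort for separation, classification and attribution
checks; ten independent 24-patient null cohorts for chance calibration;
3-seed pairs of 24-patient cohorts at effect sizes 0.4 and 1.2 for the
monotonicity property; and closed-form signals (tones, pulse trains,
shaped noise, synthetic vowels) for every extractor. The acceptance script
evaluates a 120-woman cohort at prevalence 0.642 and reports its
extreme-SUDs subgroup results alongside the closed-form significance
arithmetic.

## Known limitations

* The vowel-like source has no phonetic variation; MFCC functionals are
  therefore far more stable than on real speech.
* Chunk counts depend on the trailing-remainder and minimum-voiced rules;
  real interview recordings with long interviewer turns would behave
  differently.
* The permutation-importance fallback is not additive and is reported as an
  approximation, not as Shapley values.
* The binomial significance model treats patients as independent Bernoulli
  trials and folds as independent replicates; both are approximations.
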