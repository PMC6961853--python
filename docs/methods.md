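# Methods

`speechstate` models provider-rated clinical state in people with serious
mental illness from longitudinally collected speech samples. Each data
point is one telephone-style call: three open-ended spoken responses
(transcript + mono WAV) and a single-item global assessment rating from
the treating provider on a 1–10 scale (1 worst, 10 best). The package
extracts a fixed a-priori battery of 210 speech features per call,
characterizes their correlation structure with the ratings, and fits
cross-validated support-vector regression models of the rating — trained
either on the population (leave-one-subject-out) or on the individual's
own history (leave-one-window-out).

## Feature battery

70 features per response × 3 responses = 210 per call, keyed
`q{1,2,3}__{name}`:

- **36 norm functionals.** Nine psycholinguistic word norms (arousal,
  valence, positivity, negativity, objectivity, concreteness, age of
  acquisition, pronounceability, gender ladenness), each summarized over
  the in-vocabulary tokens of a response by mean, min, max, and
  population standard deviation (ddof = 0, so a one-word response gives
  std 0 rather than an undefined value). Out-of-vocabulary tokens are
  ignored; lexicon coverage is tracked separately. No norm extrapolation
  to unseen words is attempted.
- **15 category percentages.** LIWC-style dictionary categories (positive
  and negative emotion, anxiety, anger, sadness, overall affect,
  religion, health, body, assent, negation, swearing, social, cognitive,
  perceptual), each as 100 × matched tokens / total tokens. Dictionaries
  support literal words and `stem*` prefixes; matching is lowercase after
  punctuation stripping.
- **8 complexity features.** Flesch reading ease, Flesch–Kincaid grade,
  SMOG, Automated Readability Index, Coleman–Liau, difficult-word count,
  mean syllables per word, word count. Syllables use the standard
  dictionary-free heuristic (maximal `aeiouy` runs, silent trailing *e*,
  minimum 1); this is approximate by design and documented as such.
  Difficult words default to "more than six syllables", with the
  conventional ≥3-syllable polysyllable rule available as an option.
  Spontaneous speech is often transcribed without punctuation, so
  sentence-normalized formulas fall back to one sentence per response
  (fixed-length pseudo-sentences are available via an option).
- **2 coherence features.** A latent semantic analysis space is built
  from the cohort's own responses by default: log-entropy-weighted
  term–document matrix (tf-idf optional), deterministic truncated SVD
  (default k = 50, clipped to min(|V|, D) − 1), word vectors = left
  singular vectors scaled by singular values. Phrase vectors are means of
  in-vocabulary word vectors over sentences (or non-overlapping 10-word
  windows when unpunctuated); the coherence series is the cosine
  similarity of consecutive phrase vectors, reported as mean and
  population std. All-out-of-vocabulary phrases are skipped rather than
  treated as zero vectors; fewer than two usable phrases yields missing
  values. Coherence is computed within a response.
- **9 acoustic features.** F0 mean/median/std, F1 and F2 means, HNR
  median, pause fraction, mean pause duration, voiced fraction.

## Acoustic algorithms

The standard phonetics-toolchain algorithms are implemented on numpy so
they can be validated in a closed loop against synthesis ground truth:

- **Pitch**: framewise (40 ms window / 10 ms step) normalized
  autocorrelation, search band 75–500 Hz, voicing threshold 0.45 on the
  peak. Candidates are local maxima scored with an octave cost of
  0.05 · log2(lag / lag_min), which resolves the near-tie between the
  true period and its double; the winning peak is refined by parabolic
  interpolation (needed to reach ±2% accuracy at an 8 kHz rate).
- **Formants**: per voiced frame, pre-emphasis 0.97, Hamming window,
  linear prediction of order 2 + rate/1000 (Levinson–Durbin, batched),
  polynomial roots via batched companion-matrix eigenvalues; resonances
  with bandwidth < 400 Hz inside (90 Hz, Nyquist − 50 Hz) sorted
  ascending give F1, F2; response value = mean over voiced frames.
- **HNR**: per voiced frame 10·log10(r/(1−r)) with r the autocorrelation
  peak clipped to [1e−6, 1−1e−6]; response value = median.
- **Pauses**: framewise RMS (25 ms / 10 ms); speech frames exceed 5% of
  the 95th-percentile RMS; pauses are non-speech runs ≥ 150 ms strictly
  between speech (leading/trailing silence excluded). "Inter-word pause"
  is thus approximated by inter-speech-segment pauses from an energy VAD;
  no word alignments exist or are attempted.

All thresholds are energy-relative, so the features are invariant to
recording gain; every constant is exposed in `AcousticConfig`. Audio
defaults to telephone-grade 8 kHz 16-bit mono, but any PCM rate is
accepted.

## Correlation analyses

- **Population ranking**: Spearman rho (average ranks, t-approximate p)
  of every feature against the rating, pooled over all rated calls, with
  Bonferroni significance at alpha / n_features.
- **Individual profiles**: the 210-vector of within-person feature–rating
  rho, computed for participants with ≥ 35 rated calls; profile
  similarity is the Pearson correlation between two participants'
  vectors (missing entries dropped pairwise), averaged over all pairs.
- **Half-split stability**: calls split chronologically in half;
  per-feature rho compared across halves. The default test is Fisher
  r-to-z for independent correlations, because the halves are disjoint
  samples. A Williams/Steiger-style dependent-correlation variant is also
  shipped (halves paired by index after truncation, Pearson–Filon
  covariance term); the pairing structure for that classical test is
  genuinely ambiguous in this design, which is why the independent-sample
  test is the default. Stability = share of testable features with
  p ≥ 0.05.

## Tracking models

Features and ratings are averaged over non-overlapping windows of 4
consecutive calls (trailing remainders dropped, keeping windows
independent; within-window means are mask-aware). The regressor is
liblinear L2-regularized linear SVR (primal, squared epsilon-insensitive
loss — deterministic and robustly convergent), grid-searched over cost
C ∈ {0.01, 0.1, 1, 10} and tube width ε ∈ {0.01, 0.1, 1} in an inner
cross-validation (5 folds; grouped by participant for the population
model, sequential blocks for the personalized model) minimizing mean
absolute error — the natural inner loss for an epsilon-insensitive
regressor. Outer folds: leave-one-subject-out (population) or
leave-one-window-out (personalized; participants need ≥ 35 calls).
Forecasting pairs the features of window *t* with the rating of window
*t* + 1. Median imputation and z-standardization are fitted on each
training fold only — standardization is required for a linear margin
model over features with wildly different units, and fold-internal
statistics prevent train/test leakage (verified by dedicated tests).
Predictions are clipped to the 1–10 rating range.

Evaluation is the per-participant Spearman correlation between predicted
and actual window ratings (participants need ≥ 3 test windows), averaged
across participants; significance is a two-tailed paired t-test of the
per-participant rho against the baseline's (one-sample against zero for
the population baseline, which is "assume no correlation"; the
personalized baseline predicts each window by the leave-one-out mean of
the participant's other ratings). Assessment-scale scores (symptom or
functioning questionnaires) can replace the provider rating as the
target after nearest-call matching within 14 days (ties to the earlier
call); the model path is identical.

**Diagnosis classification** aggregates each participant's calls to one
mean feature vector and runs leave-one-subject-out linear SVC (C = 1);
the metric is unweighted average recall with a 200-draw label-permutation
p-value. Note that under the null, LOSO point estimates of UAR scatter
widely at small n and carry the known anti-learning bias; the permutation
test is the calibrated statement.

## Synthetic cohort

The generator produces the statistical structure the analysis assumes,
with known ground truth. Per participant, a latent clinical state follows
an AR(1) process s_t = μ + φ(s_{t−1} − μ) + ε on the 1–10 scale (defaults
φ = 0.85, innovation sd 0.8, μ uniform in [4, 7] — slow week-scale drift
with occasional larger excursions), and the provider rating is the state
plus Gaussian noise (sd 0.5), rounded and clipped. The state drives four
observable channels: word count (≈ 6 words per state unit around a
60-word base), positive/negative word choice (±0.055 probability per
state unit), voice pitch (6 Hz per state unit around 160 Hz), and pause
fraction (−0.05 per state unit around 0.35). In *heterogeneous* mode each
participant receives an independent random sign and weight (0.5–1.5) per
channel — so *which* features track state, and in which direction, is
individual; in *shared* mode everyone uses the identity pattern.
Diagnosis labels are drawn uniformly from four groups and carry no speech
signal by construction. Audio is synthesized as fractional-delay impulse
trains (exact average period) through 700/1200 Hz resonators with
low-level noise and silence gaps sized to the target pause fraction;
responses default to 2 s at 8 kHz. All randomness flows from one seed via
per-participant substreams.

Transcripts are statistical word salads over a bundled synthetic demo
lexicon (about 200 real everyday words with programmatically assigned
norms and 15 category memberships): sufficient to exercise every lexical
feature with known directionality, but not fluent language — no claims
about naturalistic syntax, topic structure, or transcription noise
follow from these tests. Similarly, the synthetic audio has a fixed
two-resonance vocal tract, so formant features carry no state signal by
design, and real-world channel effects (codec artifacts, background
noise, speaker overlap) are absent. Passing the end-to-end checks
therefore demonstrates that the pipeline recovers the structure it
assumes when that structure is present, not that real cohorts contain it.

## Reference studies and problem sizes

Three canonical configurations (module `speechstate.study`) are used by
the test suite and the acceptance script: a heterogeneous cohort of 12
participants × 60 calls for the personalized-vs-population contrast, a
shared cohort of 20 × 48 for population learnability, and a 47 × 20
cohort — the clinic scale of interest — for the null diagnosis
classification. These sizes exercise every code path at full feature
dimensionality while keeping a complete run in the minutes range on one
CPU.

## Numerical choices and degenerate inputs

- Spearman needs ≥ 3 complete pairs and non-constant ranks; otherwise
  missing. Fisher z needs ≥ 4 per half.
- Constant-rating participants yield undefined evaluation rho and are
  excluded (and counted) rather than imputed.
- Zero-variance features standardize with divisor 1; all-missing columns
  impute to 0 with a warning (they are inert after standardization).
- Identical rho series in the baseline comparison give p = 1.0 (no
  improvement) instead of a degenerate t-test.
- WAV integer PCM rescales by full scale (32768 for int16); multichannel
  averages to mono before rescaling.
- Known limitation: the syllable heuristic and the energy VAD are
  approximations; both are deterministic and validated only against
  their contracts, not against human annotation.
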