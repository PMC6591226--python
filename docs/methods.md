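# Methods

`ppgmiles` detects obstructive hypertrophic cardiomyopathy (oHCM) from
resting wrist photoplethysmography (PPG). A 5-minute recording is
segmented into beats, each qualified beat is described by a fixed
42-feature morphometric vector, and a multiple-instance classifier
(MILES) maps the whole recording to a single oHCM score. Because no
patient recordings accompany this package, a synthetic cohort generator
reproduces the benchmark study conditions — 19 oHCM and 64 healthy subjects, 1–5
recordings each — so that every stage is testable end to end.

## Synthetic beat and recording model

A pulse wave on one beat interval is the sum of three smooth,
log-concave components:

* a **gamma-shaped systolic wave** with mode at `crest_time` (the shape
  and scale are solved from the crest time and a width parameter);
* an optional **Gaussian mid-systolic bump**, centred at 60% of the
  crest-to-notch span, producing beats with multiple peaks of variable
  intensity;
* a **Gaussian dicrotic/diastolic wave** whose centre, width and height
  are solved in closed form so that the summed waveform has an exact
  stationary local minimum at `notch_time` with height
  `notch_ratio x pulse amplitude`.

Because the notch is an exact stationary point of the analytic model,
the generator doubles as an oracle for segmentation and feature tests:
ground truth records every onset, systolic peak and notch time.

The closed-form solve needs three guard rails, all documented model
properties rather than tuning knobs:

* the dicrotic amplitude is floored so the post-notch rebound is visible
  (standardised offset v >= 0.8) instead of a flat plateau;
* the notch height gap is capped by the beat period so the diastolic
  wave fits inside the beat;
* the dicrotic wave is cosine-tapered over the last quarter of the beat
  so a broad diastolic dome still reaches the next foot at baseline.

Recordings concatenate beats whose intervals follow a per-subject heart
rate drawn from the cohort Normal (clipped to 40–180 bpm), with
per-beat interval jitter (`ibi_cv`), per-beat multiplicative shape
jitter (`beat_to_beat_cv`), per-subject shape offsets
(`between_subject_cv`), sinusoidal respiratory amplitude and baseline
modulation, occasional "irregular" beats (shape parameters redrawn from
a 4x-widened distribution; rhythm stays sinus), and additive Gaussian
sensor noise. Default sampling rate is 64 Hz (configurable 25–250 Hz).

### What the generator does and does not emulate

It reproduces the morphological axes characteristic of oHCM — steeper and
earlier systolic rise, longer systolic ejection, multiple systolic
peaks, a spike-and-dome contour, larger beat-to-beat and respiratory
variability, higher heart rate — with clean optical coupling and no
motion. It does **not** model motion artifacts, sensor decoupling,
arrhythmia, hemodynamic (Windkessel) physiology, or age/medication
effects. Passing benchmarks therefore demonstrate that the pipeline
recovers class structure of this kind when it is present; they do not
certify performance on real wrist data.

### The frozen benchmark regime

`config/paper_regime.yaml` fixes the two classes. Heart rates follow
the benchmark cohort profile (healthy 59±9 bpm, oHCM 72±11 bpm). The morphology and
variability deltas were calibrated once against the measured 42-feature
separation and then frozen: oHCM crest 0.10 s vs 0.21 s, notch 0.37 s
vs 0.32 s, notch height ratio 0.33 vs 0.52 with a tall diastolic wave
(0.62 vs 0.30), bump amplitude 0.32 vs 0.03, beat-to-beat CV 0.14 vs
0.04, interval CV 0.08 vs 0.03, irregular-beat probability 0.08 vs
0.01, respiratory amplitude modulation 0.18 vs 0.10.
`config/null_regime.yaml` generates both labels from the identical
healthy distribution and is used for type-I-error calibration.

## Segmentation

Detection runs on a zero-phase 2nd-order Butterworth band-pass of
0.5–8 Hz; landmark measurement, beat qualification and feature
extraction use a gentler 0.3–16 Hz band, because the 8 Hz edge smears
the dicrotic notch and the 0.5 Hz edge tilts relative amplitudes.
Upstrokes are peaks of the first derivative above an adaptive threshold
(35% of the block-wise 98th percentile of the positive derivative;
the high percentile tracks systolic slopes even when long flat
diastoles dominate), separated by a 0.33 s refractory period. The foot
is the local minimum of the measurement signal in a ±3-sample
neighbourhood of the start of the derivative's positive run. The notch
is the most prominent smoothed local minimum in early diastole that
sits above the foot and is not followed by a near-systolic peak;
failing that, the first local maximum of the second derivative after
the peak (flagged as a fallback), else absent. Beats qualify when the
interval lies in [0.33, 2.0] s, the amplitude within [0.25, 4]x the
recording median, and the correlation with the length-normalised
median-beat template is >= 0.5 — deliberately loose, because irregular
beats are signal in oHCM. Recordings shorter than 30 s, or with fewer
than 10 qualified beats, are unusable.

## The 42-feature catalog

Eight timing features (interval, heart rate, crest time, systolic
ejection time, diastolic time and ratios), six amplitudes (pulse
amplitude, notch and diastolic-wave heights, normalised mean/RMS), six
slopes, five fractional widths, four areas, the a–e waves of the
second derivative with the aging index, three shape statistics
(prominent-peak count, skewness, kurtosis), and four respiratory-
context features over a ±5-beat window (relative amplitude and interval
deviation, amplitude CV, template correlation). Amplitudes are taken
after per-beat foot subtraction; normalised quantities divide by the
pulse amplitude. Missing notches fall back to the second-derivative
landmark; entries that still cannot be computed are flagged invalid and
mean-imputed per recording. The catalog is versioned and frozen.

## Group statistics

Subjects are the statistical unit: features are collapsed to per-subject
medians over all qualified beats of all recordings before testing,
which avoids pseudo-replication from hundreds of correlated beats per
person. Each feature is compared with a two-sided Mann-Whitney U test
(exact enumeration when both groups have n <= 8 and no ties, otherwise
the normal approximation with tie correction), with Cliff's delta as
the effect size and Bonferroni correction over exactly 42 tests at
alpha 0.05.

## MILES classification

Each recording is a bag of beat-feature instances. Features are
z-standardised with statistics fitted on training beats only. The
concept pool is all training instances when they number at most
`pool_cap` (default 2000), otherwise a seeded label-stratified
subsample. A bag's embedding coordinate for concept c is
`max_j exp(-||x_j - c||^2 / sigma^2)`; since exp is monotone, only the
minimum squared distance per (bag, concept) is needed, and that matrix
is computed once per pool and shared across all kernel widths.

The classifier is the 1-norm SVM: minimise mean hinge loss plus
`lambda * ||w||_1`, solved exactly as a linear program (HiGHS dual
simplex) — convex, deterministic, and sparse in the concepts it
selects. The oHCM score of a recording is the linear decision value;
no probability calibration is applied.

Hyperparameters (sigma in {2, 4, 8} standardised units, lambda in
{0.01, 0.1, 1}) are tuned with 68 seeded subject-level random splits of
the training set (70% train / 30% validate by default; a switch honours
the literal 70% test / 30% train reading). Two numerical choices make
the ~50,000 inner fits affordable: the inner loop ranks grid points
with a fast L1 squared-hinge surrogate (liblinear) on a 256-concept
subsample of the fold pool, and the shared min-distance matrix makes
each sigma an elementwise transform. Candidates are then accepted in
rank order only if the exact LP on the full training embedding yields
nonzero weights — the surrogate can rank a degenerate kernel width
(all similarities near zero) highly because exponentially ordered
margins still sort the validation bags, while the exact LP would
refuse to spend weight there and score everything with a constant.
Ties prefer the smallest sigma, then the largest lambda.

## Evaluation

Leave-one-subject-out: for each of the 83 subjects, hyperparameters are
re-tuned, the pool rebuilt and the LP refitted on the other subjects
only, and the held-out subject's recordings are scored by that model.
Pooled out-of-fold scores give a recording-level ROC; a subject's score
is the mean over their recordings, and subject-level scores drive the
C-statistic, the Youden threshold (midpoint cut maximising
sensitivity + specificity; ties resolved toward higher specificity,
then the higher threshold) and the per-person confusion matrix. The
95% CI of the subject-level AUC is a percentile bootstrap with 2000
resamples, stratified within class so every replicate keeps both
classes.

One inner-loop economy is worth naming: the tuning splits share the
fold-level concept pool rather than rebuilding a pool per split, so
inner-validation instances participate in the pool used during tuning.
The fold-level guarantee — nothing about the held-out subject touches
standardisation, pool, tuning or fit — is unaffected, and is asserted
by tests.

## Problem sizes used by the test suite

The benchmark tests run the full frozen cohort (83 subjects, 5-minute
recordings, pool cap 2000, 68 inner splits) once per session and share
the result. The null-regime calibration runs 10 seeded replicates at a
reduced scale chosen to keep the whole suite desk-sized: 12 + 20
subjects, 60 s recordings, 1–2 recordings per subject, pool cap 400,
8 inner splits. At this size the mean leave-one-out AUC under the null
sits near chance; much smaller cohorts drift pessimistic (below 0.5),
because removing the held-out subject shifts the training class balance
against that subject's class — a known property of leave-one-subject-
out pooling, visible here because the band is tight.

## Known limitations

* The notch detector degrades on plateau-like notches under noise;
  the second-derivative fallback keeps the ejection-time features
  usable but noisier for a minority of fast-heart-rate subjects.
* Absolute-slope features saturate against the 16 Hz measurement band,
  so the two decline-rate features and the width-shape ratio separate
  the synthetic classes only weakly; in the frozen benchmark 38–39 of
  the 42 features are Bonferroni-significant, the remainder being
  exactly these.
* The LP refit per fold is exact but the inner ranking is a surrogate;
  with strongly separable data the selected grid point is stable, but
  on marginal data the surrogate ranking may differ from what exact
  inner LPs would choose.
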