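# Methods

## The screening problem

Obstructive sleep apnea (OSA) and primary insomnia are the two most
common complaints arriving at a sleep clinic. OSA is graded by the
apnea-hypopnea index (AHI, events per hour of sleep): below 5 is no
apnea, 5–15 mild, 15 and above moderate-severe and treatment-relevant.
`oxiscreen` implements a two-stage triage: a questionnaire classifier
routes likely-OSA patients to an oximetry classifier that grades
severity, so that scarce polysomnography slots go to the patients most
likely to need them. The AHI is always an *input label* here — scoring
respiratory events from airflow channels is out of scope.

## Signal model and preprocessing

Input is a 1 Hz percent-saturation series (higher native rates are
reduced by per-second block means, which is robust to single-sample
spikes, unlike decimation). Three artifact rules are applied in a fixed
order:

1. values below 50% are physiologically implausible and become missing
   (50 itself is kept);
2. a sample more than 4 points below the last *accepted* sample is an
   artifact (true desaturations ramp at ≤ 4 points/s). Comparing against
   the last accepted sample means an artifactual cliff keeps masking the
   implausible low run until the signal recovers, while a gradual
   genuine event passes untouched;
3. missing runs longer than 60 s (probe disconnection, movement) split
   the record; runs of at most 60 s are bridged by linear interpolation
   so that spectral and entropy estimators see continuous segments.
   Segments shorter than 300 s are discarded: multiscale entropy at
   scale 20 and a 0.001 Hz spectral resolution are meaningless below
   that length.

Cleaning is idempotent, and the per-second-drop bound is preserved by
interpolation (descents across a bridged gap are always ≤ 4 points/s).

## The 128 oximetry features

* **Distribution (7).** Mean, median, maximum, minimum, excess
  kurtosis, population variance, skewness of all valid samples pooled
  across segments. Skewness/kurtosis use the bias-adjusted Fisher
  definitions and are defined as 0 for a constant signal.
* **Power spectral density (100).** Per segment (length ≥ 1000 s):
  mean-subtracted Welch estimate, 1000-sample Hann window, 50% overlap —
  the single window length that yields exactly 0.001 Hz bin spacing at
  1 Hz sampling. Each non-DC bin is divided by total non-DC power
  (relative power; full band sums to 1), then segments are combined by
  duration-weighted averaging. Features are bins k = 1..100
  (0.001–0.100 Hz). Relative rather than absolute power was chosen
  because the discriminative signal is the *proportion* of energy in the
  cyclic-desaturation band, not the oximeter-dependent absolute level.
  A constant segment returns all-zero bins.
* **Multiscale entropy (20).** SampEn(m = 2, r = 0.15·SD) of the
  longest segment coarse-grained at scales 1..20. The tolerance r is
  frozen at the scale-1 SD so the curve reflects coarse-graining rather
  than tolerance re-scaling; m = 2 and r = 0.15·SD are the standard
  sample-entropy defaults. Only the longest segment is used:
  coarse-graining across segment boundaries would fabricate dynamics.
  Matching uses Chebyshev distance with ≤ r, self-matches excluded;
  when no (m+1)-template pair matches, the finite cap
  ln((N−m)(N−m−1)) is returned. The implementation compresses templates
  to unique rows with multiplicities and counts pairs with a weighted
  KD-tree — exact (the suite verifies equality with an O(N²)
  brute-force oracle) and fast on quantised oximetry data.
* **ODI (1).** Running baseline = maximum saturation over the preceding
  120 s. An event starts when the signal falls ≥ 4 points below the
  baseline, ends on recovery to within 2 points of the *onset* baseline
  or after 180 s, with a 10 s refractory between events; the count is
  divided by valid recording hours. The onset baseline is frozen for
  the recovery test so a drifting window cannot prematurely terminate
  long events. Valid (artifact-free) time is the denominator because
  sleep staging is unavailable from the oximeter alone; the index is
  therefore a slight underestimate of a polysomnographic ODI when much
  of the night is artifact.

## Questionnaire features and PSQI scoring

The PSQI's 18 self-rated entries are scored into seven 0–3 components
(subjective quality, latency, duration, habitual efficiency,
disturbance, medication, daytime dysfunction) per the published
instrument (Buysse et al. 1989), summing to the 0–21 global score.
Notable conventions: exactly 7 h of sleep scores duration 1 (the
“more than 7” band is strict), 75% efficiency falls in the 75–84% band
(score 1), and the bed-time interval handles midnight wrap-around.
Item 5.10 (“other reasons”) is included as a 0–3 frequency like its
siblings. Incomplete questionnaires are rejected rather than imputed,
mirroring a screening-form context. The full feature vector is
[6 clinical, 18 items, 7 components, global] = 32 values; clock-time
items are encoded as hours since noon so typical bed times form a
contiguous range. Sex is coded male = 1 (tree models are
encoding-invariant). The reduced form is [age, sex, BMI, snoring
(item 5.5), hypertension].

## Training machinery

70/15/15 stratified split (deterministic per seed, per-class counts
within one case of exact proportionality). SMOTE (k = 5) raises every
training-partition class to the majority count by convex interpolation
between same-class nearest neighbours; validation and test partitions
are never balanced. Three ensembles are supported: gradient boosting
(300 trees, depth 3, learning rate 0.1, early-stopped at the boosting
length minimising validation log-loss), random forest and extra trees
(500 trees each). Feature importance is the split count — how often a
feature appears as a decision node across all trees — with ties broken
alphabetically. The study driver trains all three per task and keeps
the algorithm with the best validation weighted F1, the way a screening
study selects its production model. Stage 1 calls OSA at predicted
probability ≥ 0.5 (configurable); stage 2 takes the argmax severity
with ties resolved toward the more severe class, since a screen must
not miss moderate-severe disease.

Metric conventions: per-class precision/recall/F1 with a 0 convention
for empty denominators; support-weighted averages by default (weighted
recall equals accuracy algebraically, which the suite asserts on fuzzed
matrices) with macro also reported; binary AUC is the rank statistic,
multiclass AUC macro one-vs-rest.

## Synthetic cohort: what it emulates, and what it does not

The generator exists because the cohorts such screeners are built on
are access-restricted. Defaults describe a sleep-clinic population:

* **Class mix** — `clinic` preset: 33.1% insomnia / 29.4% mild /
  37.5% moderate-severe; `community` preset: 46.2 / 31.2 / 22.6 with no
  insomnia phenotype.
* **Signal** — AR(1) baseline, mean 96.5%, SD 0.35, lag-1 0.995;
  integer quantisation; 6 h records (typical in-lab total recording
  time). Desaturation events are piecewise linear (30% down-ramp, 40%
  hold, 30% recovery), 20–60 s long, 4–15 points deep — depth ≥ 4
  guarantees ODI4 detectability. Event arrivals are a refractory
  renewal process (exponential gaps shifted by 12 s) whose rate equals
  the case's latent AHI, so the planted rate is realised even at severe
  rates where a pure Poisson stream would overlap events. Artifacts:
  ~2 spikes/h to 20–45% and ~0.5 dropouts/h of 10–150 s.
* **AHI bands** — none 0–4, mild 6–14, moderate-severe 16–60 events/h.
  The deliberate gaps at 5 and 15 make the planted severity recoverable;
  real cohorts have boundary cases, so test metrics here overstate
  real-world performance near the cutpoints.
* **Questionnaires** — covariates drawn from a base population
  (age ~ N(50, 15), BMI ~ N(25.5, 4.5), half male, 25% hypertensive);
  OSA status is Bernoulli with log-odds 0.13/BMI unit, 0.35/decade,
  0.9 for male sex, 0.8/snoring level, 0.5 for hypertension, the
  intercept calibrated by bisection so the marginal OSA fraction matches
  the preset mix. Insomnia cases then receive long latencies
  (lognormal, median 45 min), poor subjective quality, short sleep and
  frequent hypnotic use; OSA cases receive breathing-related disturbance
  and daytime sleepiness.

Not modelled: REM/NREM architecture, cardiorespiratory coupling,
position effects, oximeter averaging windows, and any overlap between
insomnia and OSA phenotypes (comorbid insomnia-plus-OSA patients do not
exist in the simulation). Passing tests therefore demonstrate that the
pipeline recovers *planted* structure faithfully — not that the trained
models transfer to clinical data.

## Problem sizes and numerical choices

The packaged study runs 600 cases of 6 h each; the rate-recovery
experiment uses 2 h traces, 50 replicates per rate — sizes chosen to
make the full suite a desk-scale run on one CPU. Entropy equality with
the brute-force oracle is exact (identical ≤ r comparisons), spectral
normalisation is asserted to 1e-9, and the planted-rate recovery
tolerance (10%) absorbs the generator's known small losses: events
clipped at record boundaries, events hidden by dropouts, and
marginal-depth events quantised below the detection threshold.

## Known limitations

* The ODI approximation divides by valid recording time, not total
  sleep time, and uses the 4% criterion only (no 2%/3% variants).
* The questionnaire model is trained on insomnia-vs-OSA cohorts only;
  it has never seen healthy controls.
* Boosted-tree split-count importance dilutes across the 100 correlated
  PSD bins late in training; bagged ensembles give the more stable
  ranking (the oxygen desaturation index ranks at or near the top for
  random forest and extra trees).
* EDF support covers reading a saturation channel only; EDF writing and
  non-saturation channels are out of scope.
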