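# Methods

`gazecue` implements a complete analysis chain for a gaze-cueing experiment
in children: raw 300 Hz gaze streams and trial event logs are turned into
per-trial oculomotor and behavioral features, collapsed to a participant
feature matrix, screened with mixed models and nonparametric group tests,
and fed into a cross-validated logistic model that classifies ADHD versus
typically developing (TD) participants. Because the study data are not
deposited, the package ships a synthetic-cohort generator whose defaults
encode the study conditions; everything downstream of the generator is the
analysis a lab would run on real recordings.

## Task model

Each trial shows a central cue (a face whose eyes shift on *social* blocks,
an arrow on *nonsocial* blocks) pointing at one of the four screen corners
for 500 ms. After a stimulus onset asynchrony (SOA) of 250, 500 or 750 ms a
red target dot appears at a corner together with a blue distractor at
another corner, and the child presses the key matching the target corner.
On *congruent* trials the target sits in the cued corner; on *incongruent*
trials the distractor does. Four blocks of 36 trials alternate cue type,
with the starting cue type alternating across participants; within each
block the 3 SOA × 2 congruency cells are exactly balanced (6 trials each)
and cue corners are balanced (9 each). Stimulus centers sit 0.2 normalized
units from the screen center; coordinates are normalized `[0,1]²` with the
origin top-left.

The display is a 23″ 1920×1080 monitor viewed at 65 cm; physical size is
derived from the diagonal assuming square pixels. Normalized displacements
convert to visual angle via `2·atan(d_cm / 2 / 65 cm)`. At this geometry the
77 px stimulus subtends ≈1.8°, slightly less than the 2° nominal target
size; both are independent configuration values and the package does not
reconcile them.

## Preprocessing

1. **Smoothing.** Savitzky–Golay, polynomial order 9, window 21 samples
   (70 ms at 300 Hz), applied to x and y independently over contiguous
   valid runs. Invalid samples never enter a window; runs shorter than the
   window pass through with a warning.
2. **Velocity.** Central-difference angular speed (°/s); undefined at
   invalid samples and at run boundaries.
3. **I-VT segmentation.** Samples with velocity ≥ 30 °/s are saccadic
   (boundary inclusive), < 30 °/s fixational; run-length grouping produces
   events. Boundary samples with undefined velocity inherit their
   neighbor's label. Events shorter than 10 ms (3 samples at 300 Hz) are
   merged into the preceding event, which suppresses single-sample noise
   saccades. Invalid gaps split events, with one exception: two fixations
   separated by a gap of at most 75 ms whose centroids lie within 1° are
   rejoined. This gap bridging mirrors the fill-in stage of production I-VT
   filters; without it, brief track loss fragments fixations and
   systematically biases every duration-based measure downward in the
   high-loss group. Both the 75 ms gap and the 1° dispersion bound are
   configurable, and `max_gap_s=0` disables bridging.
4. **Calibration gate.** Three validation points, each valid if its
   accuracy error is within 2° (inclusive); a recording is excluded when
   more than one point fails.

## Per-trial features

All oculomotor measures are computed in the **target detection period**:
target onset to key response (to trial end when no key was pressed; an
anticipatory response empties the window and flags the trial).

* `rt`, `correct` — key response latency (regardless of accuracy) and hit.
* `n_saccades` — saccades whose onset falls in the window.
* `saccade_length_deg` — mean saccade amplitude in the window (a `sum`
  variant is exposed via configuration, since either reading of "saccade
  length" is defensible).
* `saccade_velocity_deg_s` — mean of per-saccade peak velocities (a mean-
  velocity variant is likewise configurable).
* `fix_dur_cue_soa` — summed fixation time inside the cue AOI between cue
  offset and target onset.
* `sd_fix_locations_deg` — `sqrt(var_x + var_y)` of fixation centroids in
  degrees: one rotation-invariant dispersion scalar per trial.
* `null_rate` — invalid-sample fraction over the whole trial.
* `per_fixation_duration` — total fixation time in the window divided by
  the number of fixations in it (undefined with zero fixations).
* `rja` (social trials only) — gaze occupies the central cue AOI at window
  start and the *first* fixation outside the AOI lands in the cued
  quadrant, with no intermediate quadrant visit. When the first window
  sample is invalid, the start condition accepts AOI occupancy within the
  preceding 100 ms.
* `peripheral` (social trials only) — every window fixation stays inside
  the cue AOI and no window saccade ends outside it: the target was handled
  by peripheral vision without an overt shift. Undefined (and excluded from
  the rate denominator) when the window contains no events.

The cue AOI is a circle of radius 0.08 normalized units at screen center —
it covers the 77 px stimulus with margin; the radius is configurable since
no canonical value exists. Quadrants are delimited by the screen midlines.

## Aggregation

One row per participant. Continuous features take the **median** over a
condition cell (cue × SOA × congruency), binary features the mean (a rate);
cells with no usable trials are missing, never zero. `rt` pools all trials;
`rt_correct` only correct ones; `rt_sd` is the SD of RT over all trials;
`null_rate`/`sd_null_rate` are the mean/SD of per-trial null rates over all
trials. The gaze-cueing effect is `GCE(feature, SOA) =
incongruent − congruent` on social trials. Columns follow
`feature.cue.soa.congruency` (e.g. `nsacc.social.0.25.cong`) and
`gce_feature.soa`.

Eligibility filters reproduce the cohort rules: ADHD rows with KARS
inattention ≤ 5 excluded; TD rows with inattention ≥ 10 or KARS total ≥ 18
excluded; any row with CARS ≥ 37 or a failed calibration gate excluded;
rows with missing covariates are flagged, not dropped. For modeling,
missing feature cells are median-imputed within group (with missingness
flags); group tests use complete cases.

## Screening statistics

Stage 1 fits each indicator with a random-intercept linear mixed model
(REML, z-tests) over the participant × condition long table: group,
congruency, SOA and cue type (full interactions) as fixed effects, with
z-scored age, CARS, CDI, STAI-C state/trait and sex (female as indicator)
as covariates. Marginal/conditional R² follow the fixed/random/residual
variance partition. When the full factorial is singular (tiny cohorts) the
model falls back to additive fixed effects, then to a flagged empty result.
Indicators with any fixed-effect or covariate p < 0.15 advance.

Stage 2 runs Mann–Whitney U tests (midranks; exact p by enumeration for
≤ 8 per group without ties, normal approximation with tie correction
otherwise) on the advancing indicators' columns, plus pooled-SD Cohen's d,
and applies Benjamini–Hochberg within that candidate set; columns with
adjusted p < 0.05 feed the classifier. Both raw and adjusted p-values are
reported, since printed tables can be read either way.

## Classification

Features are standardized and selected by **bidirectional stepwise logistic
regression driven by Rao's score test** (threshold 0.035 for entry and
removal). The score statistic for a candidate is `U²/V` with the score `U`
and the profiled information `V` evaluated at the null-restricted maximum
likelihood fit; removal tests each included feature by the score test of
re-adding it to the remaining model. Ties break by column order; collinear
candidates get p = 1 and can never enter, so duplicated columns are safe.
Quasi-separated fits are stabilized with a small ridge and flagged.

The selected model is evaluated by stratified 5-fold cross-validation
repeated 50 times. Each repetition pools out-of-fold predicted
probabilities and computes accuracy, precision, recall and F1 at the 0.5
threshold (positive class ADHD), midrank AUC, and Cohen's kappa
`(p_o − p_e)/(1 − p_e)` from the pooled confusion table; reported metrics
are means over repetitions. Pooling per repetition (rather than averaging
per-fold metrics) keeps kappa well-defined on small folds. Finally,
features that are non-significant in the full-data fit are pruned in order
of increasing |z|, each drop kept only if the mean AUC does not decrease
(strict non-decrease); an empty stepwise selection yields an intercept-only
model, which pins AUC at chance. Selection is performed on the full sample,
as in the source analysis — the optimism this induces is intentional and
should be kept in mind when reading the metrics.

## Synthetic cohort generator

The generator emulates the study's three inputs — gaze streams, trial logs,
participant table — with group-conditioned structure. Per participant,
group-level parameters are realized into traits (between-participant
heterogeneity), and a master seed fans out through `SeedSequence` spawning
so any participant or trial is reproducible in isolation.

**Gaze.** Streams alternate fixations (anchor plus 0.0015-unit isotropic
sample noise) and saccades with a logistic displacement profile whose peak
velocity is `max(84, scale·(55 + 4.5·amplitude))` °/s — main-sequence-like
growth, always at least 2.8× the 30 °/s threshold, so planned saccades are
detectable by construction. Holds at the screen center are chains of
refixations 1–2° apart inside the cue AOI, the fixational re-anchoring real
recordings show; a single second-long fixation event would otherwise make
per-fixation duration an RT surrogate. After target onset: with the group's
peripheral probability (social trials) gaze never leaves the AOI; otherwise
after an orienting latency (~0.2 s) the first shift lands in the cued
quadrant with the group's (conditional) RJA probability, else elsewhere,
and gaze then scans quadrant anchors with a goal-directedness bias until
the response.

**Responses.** Planned RT is shifted-lognormal per group; incongruent
social trials add the group's cueing cost. The key press lands at the end
of the fixation in progress when the planned RT elapses, so window
fixations are complete and the cost survives to the measured GCE. Accuracy
is a per-group Bernoulli (condition-independent — a simplification).

**Track loss.** Per-trial loss fractions are Beta draws with moments
matched to the participant's level and within-spread (unbiased at small
means, right-skewed like real dropout), laid down as ~50 ms bursts; the
loss level and its spread are set from the printed group distributions of
the null-data rate and its SD.

**Questionnaires.** Scores are floor-shifted gamma draws with moments
matched to the group mean/SD, ceiling-clipped: the floor is respected
without the upward mean bias of a clipped normal, and symptom scores get
their typical right skew. KARS total is the sum of its drawn subscales.
Calibration-validation errors are drawn per group and passed through the
actual gate.

**Ground truth.** Each trial log row records what was built (`gen_rja`,
`gen_peripheral`, `gen_n_saccades`, `gen_mean_fix_dur`, `gen_null_rate`).
`gen_mean_fix_dur` uses I-VT-consistent accounting: the sub-threshold ramp
tails of each planned saccade count as fixation time, since that is what a
velocity-threshold segmenter sees. These columns let the tests close the
loop between generator and measurement without re-deriving intent from
noisy data.

**Defaults** (ADHD / TD), chosen once from the study's printed group
distributions where available and from field-typical values otherwise:
per-fixation dwell 0.42±0.10 / 0.30±0.08 s; saccade-velocity scale 0.90 /
1.00; conditional RJA probability 0.61 / 0.73 and peripheral probability
0.64 / 0.56 (their product reproduces the printed measured rates ≈0.22 /
0.32 alongside peripheral ≈0.64 / 0.56); null-rate level 0.11±0.10 /
0.05±0.04 with within-trial SD 0.15±0.09 / 0.10±0.06; RT shift 0.25 s,
scale 0.70 s both groups (group medians did not differ in the study),
lognormal σ 0.55 / 0.35 (reproducing RT-SD ≈0.55 / 0.26); cueing cost
0.12 / 0.03 s; accuracy 0.85 / 0.97; KARS inattention 13.7±6.0 / 3.5±2.8,
hyperactivity 8.7±6.0 / 2.1±2.1, CARS 18.7±5.3 / 15.1±0.4, CDI 13.0±6.5 /
7.7±3.7, STAI-C state 33.3±6.9 / 30.6±4.9, trait 30.3±5.8 / 28.3±5.2, age
7.7±1.0 / 7.9±0.9 years, male ratio 0.842 / 0.444. Cohort sizes default to
19 / 27.

**What the generator does not emulate — and what that means for the
tests.** Feature channels are drawn independently per participant, without
the latent-severity correlations real cohorts show; combined classifiers
therefore separate the groups more cleanly (cross-validated AUC ≈0.99 on
the default cohort) than the ≈0.93 reported on real data. Passing the
end-to-end checks demonstrates that the pipeline detects and combines the
programmed group structure and stays at chance on a null cohort — not that
the specific reported performance is reproduced. Also absent: pupil and
head movement, smooth pursuit, binocular disparity, condition-dependent
accuracy, express saccades, and any visual saliency of the actual stimuli.

## Problem sizes and numerical choices

The end-to-end checks run the full study size — 19+27 participants × 144
trials at 300 Hz (~5 M samples per cohort) — once for the contrasted cohort
and once for a null cohort with identical group parameters (questionnaire
locations mid-range so the eligibility filters act symmetrically).
Calibration suites use 500 mixed-model replicates (type-I rate of the group
effect ≈5%), 100 stepwise replicates (planted-feature recovery ≥95%), and
exhaustive enumeration for the exact Mann–Whitney checks. Determinism:
every stochastic component takes an explicit seed; the pipeline is
reproducible byte-for-byte given the master seed. Logistic fits use
Newton–Raphson to |Δβ| < 1e-9 with a 1e-6 ridge inside cross-validation
folds for stability; linear-algebra failures and separation fall back to a
flagged ridge fit. The null-cohort intercept-only model shows AUC slightly
below 0.5 (≈0.44): with constant per-fold predictions, pooled out-of-fold
probabilities anti-correlate with the test-fold class mix — a known
cross-validation artifact, documented rather than hidden.

## Known limitations

* Feature selection on the full sample (before cross-validation) inflates
  metrics; this mirrors the source analysis and is deliberate.
* Per-fixation duration remains sensitive to heavy track loss (bursts
  longer than the 75 ms bridge still split fixations).
* The Mann–Whitney exact path is bypassed in the presence of ties.
* Binary-choice features (RJA, peripheral) are undefined on nonsocial
  trials and on windows with no events; their rates use the defined-trial
  denominator.
* The generator's block clock is idealized (no drift, no missed frames),
  and one cyclopean gaze stream stands in for binocular data.
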