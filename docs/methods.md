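# Methods

This note documents the generative model, the parameter choices, the
numerical decisions and the known limits of `motorfair`. Everything
here is about *synthetic* data: the package's purpose is to exercise a
fairness-audit pipeline against known ground truth, not to model
Parkinson's disease physiology faithfully.

## 1. Synthetic cohort

A cohort is a list of participants with a diagnostic label (PD /
non-PD) and four protected attributes: sex, race (binarised to White /
Non-White for auditing), device type and dominant hand.

Generation reproduces every configured **one-way margin exactly**:

* the joint (race, status) table is laid out deterministically from
  its configured cell counts;
* sex, device and hand are each assigned by a seeded permutation of an
  exact-count list (e.g. 212 "male" + 39 "female" tags shuffled over
  the 251 slots).

This makes each attribute independent of the others conditional on the
margins — there are no engineered two-way correlations. We chose this
over iterative proportional fitting of two-way tables because exact
marginal fidelity is the module's invariant, and the attribute
independence is itself useful: any group structure later observed in
model predictions must come from the session simulator, not from the
cohort's construction.

Default margins (251 participants): 99 PD / 152 non-PD (39.4% PD),
212 male / 39 female, 202 Windows / 41 Mac / 8 Linux, 176 right / 75
left-handed, race-by-status table with 51/134 White PD/non-PD and the
Non-White cells {Black 33/6, American-Indian or Alaska-Native 9/12,
Native-Hawaiian or Pacific-Islander 2/2, Asian 1/1}. These defaults
describe a typical remote-study population: one dominant operating
system, a strong male majority, few left-handed users, and small race
cells — exactly the composition that makes group-level auditing hard.
Invalid configurations (margins that do not sum to `n_total`, unknown
categories, negative cells) raise `CohortConfigError` naming the
offending margin.

## 2. Session simulator

Each participant performs a 7-task battery: 3 tracing shapes x 3
difficulty levels, 3 key-press tasks x 3 levels, one click-target run
(10 targets), one digit-span memory run.

**Tracing.** The pointer follows the task centerline (horizontal line;
sine wave with level-dependent amplitude `0.08 * H * level` and
`1 + level` cycles; Archimedean spiral with maximum radius
`0.35 * min(W, H)`) plus a stationary AR(1) offset sampled at 60 Hz:

    offset_t = rho * offset_{t-1} + e_t,   rho = 0.9,
    sd(offset) = base_noise_sd = 4 px.

AR(1) was chosen as the simplest process giving realistic
low-frequency pointer drift rather than white jitter; the marginal
standard deviation (not the innovation s.d.) is the configured noise
parameter, so configured effect sizes act directly on observable
deviation amplitude. For PD participants a sinusoidal tremor of
amplitude 6 px at 5 Hz (centre of the reported 4–6 Hz PD rest-tremor
band) and random phase is added, and the offset is applied radially
for the spiral so deviations stay radial by construction.

**Key tasks.** 10 prompts per level, 1.5 s apart, from alphabets
{f}, {f, j}, {a..l}; response time = `base_rt_ms` (450 ms) + Gaussian
noise (60 ms s.d., floored at 50 ms) and a false-press probability of
`base_false_press_rate` (0.02).

**Click task.** 10 targets at uniform positions; click latency is
1.2x the key-task response time; the click lands a Gaussian offset
(the participant's pointer noise s.d.) from the target and counts as a
hit within 30 px.

**Memory task.** Digit span from length 3 upward; success probability
is logistic in (length − capacity), capacity 7 digits, stopping at the
first failure.

**Effects.** All group and disease structure enters through
`EffectConfig`:

| parameter | default | unit | role |
|---|---|---|---|
| `pd_deviation_scale` | 1.8 | x | PD tracing-noise multiplier |
| `pd_tremor_amp` / `pd_tremor_freq` | 6 / 5 | px / Hz | PD tremor |
| `pd_time_scale` | 1.3 | x | PD slowing of durations and RTs |
| `pd_false_press_boost` | 0.06 | prob. | extra PD false presses |
| `pd_memory_penalty` | 1.0 | digits | PD span reduction |
| `device_latency_ms` | 0 per device | ms | additive input latency |
| `device_noise_scale` | 1 per device | x | device pointer-noise multiplier |
| `device_pd_signal_scale` | 1 per device | x in [0, 1] | attenuation of *all* PD effects on a device |
| `hand_nondominant_penalty` | 1.0 | x | noise multiplier for non-task-hand users |
| `subject_noise_cv` / `subject_time_cv` | 0.25 / 0.15 | CV | between-subject lognormal baselines |

Defaults carry a moderate disease signal and **no** group effects.
`EffectConfig.null()` turns every effect off (full exchangeability —
used by the distributional property tests); `EffectConfig.group_null()`
keeps the disease signal but no group effects (used by the audit
calibration experiments, where a disease signal is needed for the
classifier's positive rate to be meaningful).
`device_pd_signal_scale` is the bias-injection knob: scale 0 on a
device makes its PD users statistically identical to its controls.

Between-subject heterogeneity comes from per-person lognormal
baseline multipliers with mean 1 (CV 0.25 for noise, 0.15 for tempo).
Without them every participant of a group would share one
distribution, any mean shift would be perfectly separable, and
classifier AUROCs would saturate at 1.0; the CVs were set to bring
the default-condition AUROC below ceiling while keeping the disease
signal clearly learnable.

Determinism: each session derives its random streams from
`SeedSequence([seed, fnv1a(participant_id)])` with one spawned child
per task, so sessions are independent across participants, stable
across platforms, and insertion of a new task does not shift the
streams of existing ones. The same pattern governs the pipeline
(`stage_seed(seed, stage_name)`).

## 3. Features (79)

The registry (`FeatureRegistry.default()`, written by the pipeline as
`feature_registry_v1.csv`) holds 79 named features:

* per tracing shape (3): 7 deviation statistics (total, net, maximum,
  average absolute, mean signed, s.d. — as percentages or fractions of
  screen height — and maximum pixel deviation), points inside a ±15 px
  band, raw and width-normalised tracing time, and 4 kinematic
  statistics (mean/max speed, path length, sample count) = 42;
* 2 tracing aggregates (average time, average points inside);
* per key task (3): average/s.d./min/max response time, correct press
  count, correct press rate, false press count and ratio = 24;
* 2 keyboard aggregates;
* 3 click features (total click time, total reaction time over hits,
  hit rate);
* 2 memory features (maximum length reached, error count);
* 4 demographic attributes (sex, binarised race, device, hand).

Deviations are vertical offsets for the straight line and sine wave
and radial offsets (distance minus the centerline radius at the
unwrapped angle) for the spiral. Sine-wave samples outside the
horizontal task window are excluded and counted. Key presses are
matched to prompts first-unconsumed-at-or-after; a press before its
prompt is never matched. Missing values are NaN plus an explicit
missing mask — never silent zeros.

## 4. Preprocessing

70/30 split stratified on the label (`train_test_split`), then median
imputation and min–max scaling **fitted on the training partition
only** (constant columns map to 0; test values may leave [0, 1]).
SMOTE is implemented in-package (the environment does not ship
`imbalanced-learn`): each synthetic minority row is
`x + u * (x_nn - x)` for a uniform `u` and one of the k = 5 nearest
minority neighbours (scikit-learn `NearestNeighbors`), with Linux rows
excluded beforehand and synthetic rows marked in a provenance column.
A minority class of fewer than k+1 rows raises an error advising a
smaller k. Race resampling duplicates Non-White rows of the
configured status (default non-PD) with replacement up to parity with
the White subgroup. In the default pipeline both resamplers run on
the training partition only; `resample_scope: all` reproduces the
leakage-prone variant deliberately (for studying its effect) and is
documented as such.

## 5. Models and audit

Six classical classifiers at library defaults (random forest, XGBoost,
LightGBM, logistic regression with `max_iter=2000`, SVC with
probabilities, kNN) are compared by paired 5-fold stratified CV; the
top 3 by mean F1 (ties: AUROC, then id) are refit and scored on the
held-out test set. Prediction tables carry the cohort's group
attributes — never the model's inputs — so the audit cannot be fooled
by resampled or encoded columns.

Fairness metrics (unprivileged u over privileged p; defaults male,
White, Mac, right-handed privileged):

* disparate impact `DI = [(TP_u+FP_u)/N_u] / [(TP_p+FP_p)/N_p]`,
* equal opportunity `EO = TPR_u / TPR_p`,
* equalized odds `EOdds = max(|TPR_u-TPR_p|, |FPR_u-FPR_p|)`
  (`mode="signed"` gives the literal signed max, which can be negative
  and rewards a *better* unprivileged TPR; the absolute form is the
  default because 0 should mean parity).

Zero-denominator metrics are NaN, never silently 0. AUROC uses the
Mann–Whitney rank formulation with ties counted one half.

Error bars: B = 100 balanced bootstrap replicates, each drawing m rows
with replacement per group. The default m is the smaller group's
size: drawing more rows than a group holds would understate the
uncertainty of its metrics and make the significance flags
anti-conservative for small groups. Replicates where a metric is
undefined are counted and excluded. A metric is flagged significant
when the percentile interval of the unprivileged-minus-privileged
difference excludes zero; with fewer than 30 valid replicates the flag
is `None` (undecidable), not `False`.

## 6. Power analysis

Hanley–McNeil (1982) closed-form AUROC variance with fractional group
sizes `prevalence * n` and `(1-prevalence) * n` (no rounding), scanning
n upward for the smallest integer whose two-sided CI half-width meets
the target. With AUROC 0.91, prevalence 0.39, width 0.125 and 95%
confidence the minimum is **n = 111**.

## 7. Calibration experiments

The audit machinery is validated on a *designed* cohort, not the study
cohort: 400 participants balanced 50/50 on sex, device (Windows/Mac),
hand and binarised race with 40% PD prevalence
(`balanced_cohort_config`). The study-shaped default cohort has ~12
Mac users in a 30% test split — far too few for a positive-rate ratio
to carry a usable confidence interval, regardless of the effect size.

The experiment harness is deliberately plain: stratified split →
scaling → one classifier on motor features only, with no resampling
and no demographic inputs, so the only group structure that can reach
the predictions is what the simulator injected. The split is
stratified on label x (sex, device, hand): otherwise chance disease-
composition imbalance between groups in the test set — a variance
component the within-group bootstrap deliberately conditions away —
masquerades as disparity in roughly one null seed in twelve. Race is
left out of the stratification key to keep every stratum comfortably
above the minimum size.

* **Recovery:** with `device_pd_signal_scale["Windows"] = 0` (PD users
  on Windows indistinguishable from controls), the audited disparate
  impact falls well below 1 with a CI excluding 1 (20/20 seeds in the
  acceptance run).
* **Calibration:** under `group_null` effects, the device DI CI
  contains 1 and the significance flags fire at well below their
  nominal rate across 100 seeds.

## 8. Known limitations

* The simulator is a caricature: no fatigue, learning, pauses, or
  correlated task performance beyond the two subject-level
  multipliers; tremor is a pure sinusoid; devices differ only through
  the three configured knobs.
* Cohort attributes are independent by construction; real cohorts
  have correlated demographics, so real-data audits face confounding
  this synthetic audit does not.
* The balanced-bootstrap CI is conditional on the realized sample's
  group composition; it quantifies resampling noise, not
  cohort-sampling noise (hence the stratified split in the
  calibration experiments).
* SMOTE operates in the scaled feature space on numeric columns only;
  categorical columns of synthetic rows are copied from the seed row.
* Performance numbers on the synthetic default configuration (AUROC
  close to 1) are not comparable to any real study's figures; the
  synthetic disease signal is cleaner than real motor data.
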