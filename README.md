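# motorfair

Fairness audit of a simulated remote Parkinson's disease (PD) motor
assessment.

Remote, browser-based motor batteries — tracing shapes with the mouse,
timed key presses, click targets, digit-span memory — can screen for PD
at scale, but the hardware and demographics of the people taking them
are not balanced: most participants use one operating system, most are
male, most are right-handed. A classifier trained on such data can look
accurate overall while behaving very differently across those groups.
`motorfair` builds the entire audit loop on *synthetic* data so every
step is reproducible and the ground truth of any injected bias is known:

1. **Cohort** (`motorfair.cohort`) — a demographically structured
   synthetic population (default: 251 participants, 99 PD / 152
   non-PD, 212 male / 39 female, 202 Windows / 41 Mac / 8 Linux,
   176 right- / 75 left-handed) reproducing every configured one-way
   margin exactly.
2. **Simulator** (`motorfair.simulate`) — per-participant interaction
   sessions: 3 tracing shapes x 3 difficulty levels (AR(1) pointer
   noise, 5 Hz sinusoidal tremor for PD), 3 key-press tasks x 3
   levels, a click-target run and a digit-span run. Disease, device,
   and handedness effects are all injectable and individually
   switchable.
3. **Features** (`motorfair.features`) — 79 named motor/cognitive
   features (centerline deviations, tracing times, kinematics,
   response times, false presses, click latencies, memory span,
   demographics), emitted in a versioned registry order with explicit
   missing-value masks.
4. **Preprocessing** (`motorfair.preprocessing`) — stratified 70/30
   split, median imputation + min-max scaling fitted on the training
   partition only, SMOTE class balancing (implemented in-package),
   and race-subgroup resampling.
5. **Models** (`motorfair.modeling`) — six classical classifiers
   (random forest, XGBoost, LightGBM, logistic regression, SVM, kNN),
   5-fold cross-validation, top-3 selection by F1.
6. **Fairness audit** (`motorfair.fairness`) — disparate impact, equal
   opportunity and equalized odds across sex, race, device and
   handedness, with a 100-replicate group-balanced bootstrap and
   percentile-CI significance flags.
7. **Power analysis** (`motorfair.power`) — Hanley–McNeil minimum
   sample size for an AUROC confidence interval.
8. **Calibration experiments** (`motorfair.experiments`) — injected
   device-bias recovery and null-simulator calibration of the audit on
   a group-balanced designed cohort.

## Quick start

```python
from motorfair import (
    CohortConfig, EffectConfig, generate_cohort, simulate_cohort_sessions,
    extract_feature_table, attach_labels, split, fit_transform,
    smote_upsample, race_upsample, ModelSpec, fit_predict, audit_predictions,
)
from motorfair.preprocessing import SplitSpec, one_hot_encode

cohort = generate_cohort(CohortConfig(seed=1))
sessions = simulate_cohort_sessions(cohort, EffectConfig(), seed=1)
data = attach_labels(extract_feature_table(sessions, cohort), cohort)

train, test = split(data, SplitSpec(seed=1))
train = race_upsample(train, seed=1)
train, test, _ = fit_transform(train, test, encode_categoricals=False)
train = smote_upsample(train, seed=1)
train, test = one_hot_encode(train, test)

preds = fit_predict(ModelSpec("random_forest", seed=1), train, test, cohort)
report = audit_predictions(preds, B=100, seed=1)
print(report["device"]["point"])
```

prints (seed 1):

```
{'disparate_impact': 1.0111111111111113, 'equal_opportunity': 1.0, 'equalized_odds': 0.05555555555555558}
```

The whole pipeline is also available as one call (`run_all`) or from the
command line:

```bash
motorfair run --config config.yaml --seed 1
motorfair power --auc 0.91 --prevalence 0.39   # -> 111
```

An empty YAML config gives the defaults; any unknown key is rejected.
See `motorfair.pipeline.RunConfig` for every field.

## Bias injection and recovery

The audit is validated against ground truth: suppress the PD motor
signal on Windows machines in the simulator, run the plain harness on a
group-balanced cohort, and the audit must report disparate impact < 1
with a bootstrap CI excluding 1 — while under a group-null simulator
the CI must contain 1 and significance flags must stay quiet:

```python
from motorfair import run_audit_experiment, injection_effects, null_effects

r = run_audit_experiment(0, injection_effects(), attributes=("device",))
print(r.di["device"], r.di_ci["device"])   # seed 0: 0.308 (0.133, 0.532)
```

## Tests and reproduction

```bash
python -m pytest -q                 # full suite, includes the acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion,
including the 20-seed injected-bias recovery run and the 100-seed null
calibration of CIs and significance flags. The statistical criteria
simulate ~120 cohorts and take a few minutes; everything else runs in
seconds. All randomness flows from explicit seeds through per-stage
seed derivation (`motorfair.pipeline.stage_seed`), so any run is
reproducible bit-for-bit from its config.

See `docs/methods.md` for model assumptions, parameter tables and
design decisions.
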