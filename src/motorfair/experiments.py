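"""Designed calibration experiments for the fairness audit.

Two questions the audit machinery must answer before its reports can be
trusted on real runs:

* **Recovery** — if the simulator injects a known device bias (the PD
  motor signal suppressed on one device), does the audit detect it
  (disparate impact < 1 with a bootstrap CI excluding 1)?
* **Calibration** — under a group-null simulator (disease signal on,
  every group effect off), do the bootstrap CIs contain 1 and do the
  significance flags stay quiet at roughly their nominal rate?

These are power questions, so they run on a *designed* cohort, not the
study cohort: the study population has only 41 Mac users (about 12 in a
30% test split), far too few for a positive-rate ratio to have a usable
confidence interval.  :func:`balanced_cohort_config` builds a cohort
balanced 50/50 on every audited attribute, sized so each test-split
group holds ~50-60 participants.  The harness is deliberately plain —
split, scale, train one classifier on motor features only — so that the
only group structure in the predictions is what the simulator injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from .cohort import NON_PD, PD, CohortConfig, generate_cohort
from .fairness import (
    BootstrapResult,
    bootstrap_group_metrics,
    disparate_impact,
    significance_flags,
)
from .features import extract_feature_table
from .modeling import ModelSpec, fit_predict
from .pipeline import stage_seed
from .preprocessing import (
    ID_COL,
    SplitSpec,
    attach_labels,
    fit_transform,
    one_hot_encode,
    split,
)
from .simulate import EffectConfig, simulate_cohort_sessions

AUDIT_ATTRIBUTES = ("sex", "race", "device", "hand")


def balanced_cohort_config(seed: int = 0, n_total: int = 400) -> CohortConfig:
    """Cohort balanced 50/50 on sex, device (Windows/Mac), hand and
    binarised race, with 40% PD prevalence.

    ``n_total`` must be divisible by 20 so every margin is integral.
    """
    if n_total % 20 != 0:
        raise ValueError("n_total must be divisible by 20")
    half = n_total // 2
    n_pd = (2 * n_total) // 5
    n_ctl = n_total - n_pd
    # White = half the cohort; the Non-White half split 6:2:1:1 across
    # the remaining races, proportionally within each status.
    def race_cells(n_status: int) -> Dict[str, int]:
        white = n_status // 2
        rest = n_status - white
        black = (rest * 6) // 10
        amind = (rest * 2) // 10
        asian = (rest * 1) // 10
        nh = rest - black - amind - asian
        return {
            "White": white,
            "Black": black,
            "American-Indian/Alaska-Native": amind,
            "Asian": asian,
            "Native-Hawaiian/Pacific-Islander": nh,
        }

    race_by_status: Dict[Tuple[str, str], int] = {}
    for status, n_status in ((PD, n_pd), (NON_PD, n_ctl)):
        for race, c in race_cells(n_status).items():
            race_by_status[(race, status)] = c
    return CohortConfig(
        n_total=n_total,
        n_pd=n_pd,
        sex_counts={"male": half, "female": n_total - half},
        device_counts={"Windows": half, "Mac": n_total - half, "Linux": 0},
        hand_counts={"right": half, "left": n_total - half},
        race_by_status=race_by_status,
        seed=seed,
    )


@dataclass
class ExperimentResult:
    """Audit outcome of one simulated run."""

    seed: int
    predictions: pd.DataFrame
    bootstrap: Dict[str, BootstrapResult]
    di: Dict[str, float]
    di_ci: Dict[str, Tuple[float, float]]
    flags: Dict[str, Dict[str, Optional[bool]]]

    def di_ci_excludes_one(self, attribute: str) -> bool:
        lo, hi = self.di_ci[attribute]
        return hi < 1.0 or lo > 1.0

    def di_ci_contains_one(self, attribute: str) -> bool:
        lo, hi = self.di_ci[attribute]
        return lo <= 1.0 <= hi


def run_audit_experiment(
    seed: int,
    effects: EffectConfig,
    cohort_config: Optional[CohortConfig] = None,
    attributes: Sequence[str] = AUDIT_ATTRIBUTES,
    model_id: str = "random_forest",
    B: int = 100,
    alpha: float = 0.05,
) -> ExperimentResult:
    """Simulate one cohort, train the plain harness and audit it.

    The harness keeps only the motor/cognitive features (no demographic
    columns reach the classifier) and applies no resampling, so group
    differences in the predictions can come only from the simulator.
    The train/test split is stratified on label x (sex, device, hand) so
    the test-set disease composition is equal across groups by design —
    otherwise random composition imbalance, which the within-group
    bootstrap conditions away, would masquerade as disparity.
    """
    cfg = cohort_config or balanced_cohort_config(stage_seed(seed, "cohort"))
    cohort = generate_cohort(cfg)
    sessions = simulate_cohort_sessions(
        cohort, effects, seed=stage_seed(seed, "simulate"))
    features = extract_feature_table(sessions, cohort, include_demographics=False)
    data = attach_labels(features, cohort)
    by_id = {p.id: f"{p.label}|{p.sex}|{p.device}|{p.hand}" for p in cohort}
    data["_stratum"] = data[ID_COL].map(by_id)
    train, test = split(
        data,
        SplitSpec(seed=stage_seed(seed, "split"), stratify_on="_stratum"))
    train = train.drop(columns="_stratum")
    test = test.drop(columns="_stratum")
    train, test, _ = fit_transform(train, test, encode_categoricals=False)
    train, test = one_hot_encode(train, test)
    preds = fit_predict(
        ModelSpec(model_id, seed=stage_seed(seed, "model")), train, test, cohort)

    bootstrap: Dict[str, BootstrapResult] = {}
    di: Dict[str, float] = {}
    di_ci: Dict[str, Tuple[float, float]] = {}
    flags: Dict[str, Dict[str, Optional[bool]]] = {}
    for i, attr in enumerate(attributes):
        res = bootstrap_group_metrics(
            preds, attr, B=B, seed=stage_seed(seed, f"bootstrap/{attr}"))
        bootstrap[attr] = res
        di[attr] = disparate_impact(preds, attr)
        di_ci[attr] = res.fairness_ci("disparate_impact", alpha=alpha)
        flags[attr] = significance_flags(res, alpha=alpha)
    return ExperimentResult(seed, preds, bootstrap, di, di_ci, flags)


def injection_effects(device: str = "Windows", scale: float = 0.0) -> EffectConfig:
    """Study-default effects with the PD signal suppressed on ``device``.

    ``scale=0.0`` removes the device's PD motor signal entirely — the
    canonical injected bias for the recovery experiment.
    """
    return EffectConfig().with_device_suppression(device, scale)


def null_effects() -> EffectConfig:
    """Group-null effects: disease signal on, all group effects off."""
    return EffectConfig.group_null()


def detection_rate(
    seeds: Sequence[int],
    effects: Optional[EffectConfig] = None,
    attribute: str = "device",
    **kwargs,
) -> Tuple[int, list]:
    """Count seeds whose DI bootstrap CI lies entirely below 1."""
    effects = effects or injection_effects()
    results = [run_audit_experiment(s, effects, attributes=(attribute,), **kwargs)
               for s in seeds]
    hits = sum(
        1 for r in results
        if r.di[attribute] < 1.0 and r.di_ci[attribute][1] < 1.0
    )
    return hits, results


def null_coverage(
    seeds: Sequence[int],
    attribute: str = "device",
    attributes: Sequence[str] = AUDIT_ATTRIBUTES,
    **kwargs,
) -> Tuple[int, int, int, list]:
    """Null-simulator calibration over ``seeds``.

    Returns ``(n_contain, n_flags_fired, n_flags_total, results)`` where
    ``n_contain`` counts seeds whose DI CI for ``attribute`` contains 1
    and the flag counts pool every defined significance flag across
    ``attributes``.
    """
    results = [run_audit_experiment(s, null_effects(), attributes=attributes,
                                    **kwargs)
               for s in seeds]
    n_contain = sum(1 for r in results if r.di_ci_contains_one(attribute))
    fired = total = 0
    for r in results:
        for attr_flags in r.flags.values():
            fired += sum(1 for v in attr_flags.values() if v is True)
            total += sum(1 for v in attr_flags.values() if v is not None)
    return n_contain, fired, total, results
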