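"""End-to-end run orchestration: simulate -> extract -> resample ->
train -> audit, with a validated config and a reproducible manifest.

One global seed governs the run; every stage derives its own seed from
it and the stage name, so inserting a stage never silently shifts the
randomness of the stages downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .cohort import CohortConfig, generate_cohort, write_cohort_csv
from .fairness import audit_predictions, default_privilege_map, report_to_markdown
from .features import FeatureRegistry, extract_feature_table
from .modeling import default_model_specs, cross_validate, fit_predict, select_top, MODEL_IDS, ModelSpec
from .preprocessing import (
    GROUP_COLS,
    SplitSpec,
    attach_labels,
    drop_sparse_rows,
    fit_transform,
    one_hot_encode,
    race_upsample,
    smote_upsample,
    split,
)
from .simulate import DEFAULT_SCREEN, EffectConfig, simulate_cohort_sessions
from .session import write_sessions_jsonl

log = logging.getLogger("motorfair")


class ConfigError(ValueError):
    pass


def stage_seed(seed: int, stage: str) -> int:
    """Derived per-stage seed, stable across runs and platforms."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    seed: Optional[int] = None
    out_dir: str = "runs/latest"
    screen: Tuple[int, int] = DEFAULT_SCREEN
    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    train_fraction: float = 0.7
    smote_k: int = 5
    race_upsample_enabled: bool = True
    race_upsample_ratio: float = 1.0
    resample_scope: str = "train"  # "train" (leakage-safe) or "all"
    include_demographics: bool = True
    include_memory: bool = True
    models: List[str] = field(default_factory=lambda: list(MODEL_IDS))
    top_k: int = 3
    threshold: float = 0.5
    bootstrap_B: int = 100
    alpha: float = 0.05
    eodds_mode: str = "absolute"

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.smote_k < 1:
            raise ConfigError("smote_k must be >= 1")
        if self.resample_scope not in ("train", "all"):
            raise ConfigError("resample_scope must be 'train' or 'all'")
        if self.top_k > len(self.models):
            raise ConfigError("top_k exceeds number of models")
        unknown = [m for m in self.models if m not in MODEL_IDS]
        if unknown:
            raise ConfigError(f"unknown models {unknown}; known: {MODEL_IDS}")
        self.cohort.validate()
        self.effects.validate()


_TOP_KEYS = {
    "seed", "out_dir", "screen", "cohort", "effects", "split", "smote",
    "race_upsample", "resample_scope", "include_demographics",
    "include_memory", "models", "top_k", "threshold", "audit",
}


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected
    and all defaults materialised.  An empty file yields the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    cfg = RunConfig()
    cfg.seed = raw.get("seed", cfg.seed)
    cfg.out_dir = raw.get("out_dir", cfg.out_dir)
    if "screen" in raw:
        cfg.screen = tuple(raw["screen"])
    if "cohort" in raw:
        known = set(CohortConfig.__dataclass_fields__)
        bad = set(raw["cohort"]) - known
        if bad:
            raise ConfigError(f"unknown cohort keys: {sorted(bad)}")
        kwargs = dict(raw["cohort"])
        if "race_by_status" in kwargs:
            # YAML mappings cannot hold tuple keys; accept "Race|status"
            table = {}
            for key, count in kwargs["race_by_status"].items():
                if isinstance(key, str):
                    race, _, status = key.partition("|")
                    if not status:
                        raise ConfigError(
                            f"race_by_status key {key!r} must be 'race|status'")
                    key = (race, status)
                table[key] = count
            kwargs["race_by_status"] = table
        cfg.cohort = CohortConfig(**kwargs)
    if "effects" in raw:
        known = set(EffectConfig.__dataclass_fields__)
        bad = set(raw["effects"]) - known
        if bad:
            raise ConfigError(f"unknown effects keys: {sorted(bad)}")
        cfg.effects = EffectConfig(**raw["effects"])
    if "split" in raw:
        cfg.train_fraction = raw["split"].get("train_fraction", cfg.train_fraction)
    if "smote" in raw:
        cfg.smote_k = raw["smote"].get("k", cfg.smote_k)
        if cfg.smote_k < 1:
            raise ConfigError("smote.k must be >= 1")
    if "race_upsample" in raw:
        cfg.race_upsample_enabled = raw["race_upsample"].get(
            "enabled", cfg.race_upsample_enabled)
        cfg.race_upsample_ratio = raw["race_upsample"].get(
            "ratio", cfg.race_upsample_ratio)
    cfg.resample_scope = raw.get("resample_scope", cfg.resample_scope)
    cfg.include_demographics = raw.get("include_demographics", cfg.include_demographics)
    cfg.include_memory = raw.get("include_memory", cfg.include_memory)
    cfg.models = list(raw.get("models", cfg.models))
    cfg.top_k = raw.get("top_k", cfg.top_k)
    cfg.threshold = raw.get("threshold", cfg.threshold)
    if "audit" in raw:
        cfg.bootstrap_B = raw["audit"].get("B", cfg.bootstrap_B)
        cfg.alpha = raw["audit"].get("alpha", cfg.alpha)
        cfg.eodds_mode = raw["audit"].get("eodds_mode", cfg.eodds_mode)
    cfg.validate()
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Dict[str, object]:
    """Execute the whole pipeline and return the run manifest."""
    if config.seed is None:
        raise ConfigError("config must set a seed before running")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}

    # -- simulate ------------------------------------------------------------
    cohort_cfg = config.cohort
    cohort_cfg.seed = stage_seed(config.seed, "cohort")
    cohort = generate_cohort(cohort_cfg)
    log.info("stage=cohort n=%d", len(cohort))
    outputs["cohort"] = out / "cohort.csv"
    write_cohort_csv(cohort, outputs["cohort"])

    sessions = simulate_cohort_sessions(
        cohort, config.effects, config.screen, stage_seed(config.seed, "simulate"))
    outputs["sessions"] = out / "sessions.jsonl"
    write_sessions_jsonl(sessions, outputs["sessions"])
    log.info("stage=simulate sessions=%d", len(sessions))

    # -- extract -------------------------------------------------------------
    registry = FeatureRegistry.default()
    outputs["registry"] = out / "feature_registry_v1.csv"
    registry.to_csv(outputs["registry"])
    features = extract_feature_table(
        sessions, cohort, registry,
        include_demographics=config.include_demographics,
        include_memory=config.include_memory,
    )
    outputs["features"] = out / "features.csv"
    features.to_csv(outputs["features"], index=False)
    log.info("stage=extract rows=%d cols=%d", *features.shape)

    # -- resample + preprocess ----------------------------------------------
    data = attach_labels(features, cohort)
    if config.include_demographics is False:
        # group columns are still needed for race resampling and the
        # SMOTE device exclusion; they are dropped again before encoding
        by_id = {p.id: p for p in cohort}
        for col in GROUP_COLS:
            data[col] = [getattr(by_id[i], col) for i in data["participant_id"]]
    data = drop_sparse_rows(data)

    if config.resample_scope == "all":
        if config.race_upsample_enabled:
            data = race_upsample(data, stage_seed(config.seed, "race"),
                                 config.race_upsample_ratio)
        train, test = split(data, SplitSpec(config.train_fraction,
                                            seed=stage_seed(config.seed, "split")))
        train, test, _ = fit_transform(train, test, encode_categoricals=False)
        train = smote_upsample(train, config.smote_k,
                               stage_seed(config.seed, "smote"))
    else:
        train, test = split(data, SplitSpec(config.train_fraction,
                                            seed=stage_seed(config.seed, "split")))
        if config.race_upsample_enabled:
            train = race_upsample(train, stage_seed(config.seed, "race"),
                                  config.race_upsample_ratio)
        train, test, _ = fit_transform(train, test, encode_categoricals=False)
        train = smote_upsample(train, config.smote_k,
                               stage_seed(config.seed, "smote"))
    if config.include_demographics is False:
        train = train.drop(columns=[c for c in GROUP_COLS if c in train.columns])
        test = test.drop(columns=[c for c in GROUP_COLS if c in test.columns])
    train, test = one_hot_encode(train, test)
    log.info("stage=resample train=%d test=%d", len(train), len(test))

    # -- train ---------------------------------------------------------------
    model_seed = stage_seed(config.seed, "model")
    specs = [ModelSpec(m, seed=model_seed) for m in config.models]
    cv = cross_validate(train, specs, seed=stage_seed(config.seed, "cv"))
    top = select_top(cv, k=config.top_k, specs=specs)
    cv_summary = {
        r.model_id: {"mean_f1": r.mean_f1, "std_f1": r.std_f1,
                     "mean_auroc": r.mean_auroc, "std_auroc": r.std_auroc}
        for r in cv
    }
    log.info("stage=train top=%s", [s.model_id for s in top])

    reports: Dict[str, dict] = {}
    for spec in top:
        preds = fit_predict(spec, train, test, cohort, config.threshold)
        path = out / f"preds_{spec.model_id}.csv"
        outputs[f"preds_{spec.model_id}"] = path
        preds.to_csv(path, index=False)
        reports[spec.model_id] = audit_predictions(
            preds, default_privilege_map(), B=config.bootstrap_B,
            alpha=config.alpha, seed=stage_seed(config.seed, "audit"),
            eodds_mode=config.eodds_mode,
        )
    log.info("stage=audit models=%d", len(reports))

    outputs["report_json"] = out / "report.json"
    with open(outputs["report_json"], "w") as fh:
        json.dump({"cv": cv_summary, "audit": reports}, fh, indent=2, default=float)
    outputs["report_md"] = out / "report.md"
    md = "\n\n".join(
        report_to_markdown(r, title=f"Fairness audit — {m}")
        for m, r in reports.items()
    )
    outputs["report_md"].write_text(md)

    manifest = {
        "config": _config_snapshot(config),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "digests": {k: _digest(v) for k, v in outputs.items()},
        "top_models": [s.model_id for s in top],
        "cv": cv_summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _config_snapshot(config: RunConfig) -> dict:
    snap = asdict(config)
    snap["cohort"]["race_by_status"] = {
        f"{race}|{status}": c
        for (race, status), c in config.cohort.race_by_status.items()
    }
    return snap
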