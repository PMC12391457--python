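"""Classifier suite, cross-validation model selection and held-out predictions.

Six classical classifiers compete under 5-fold stratified
cross-validation on the training partition (paired folds, so every model
sees the same splits); the top three by mean F1 (ties broken by mean
AUROC, then lexicographically) are refit on the full training partition
and scored on the held-out test rows.  The PD class is the positive
class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cohort import PD, Participant
from .preprocessing import ID_COL, LABEL_COL, PROVENANCE_COL, numeric_feature_columns

MODEL_IDS = ("random_forest", "xgboost", "lightgbm", "logreg", "svm", "knn")

PREDICTION_COLUMNS = (
    "participant_id", "label", "score", "predicted",
    "sex", "race_binary", "device", "hand",
)


class ModelingError(ValueError):
    pass


@dataclass
class ModelSpec:
    model_id: str
    hyperparameters: Dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ModelingError(
                f"unknown model_id {self.model_id!r}; known: {MODEL_IDS}"
            )

    def build(self):
        p = dict(self.hyperparameters)
        if self.model_id == "random_forest":
            return RandomForestClassifier(random_state=self.seed, **p)
        if self.model_id == "xgboost":
            from xgboost import XGBClassifier
            p.setdefault("eval_metric", "logloss")
            p.setdefault("verbosity", 0)
            return XGBClassifier(random_state=self.seed, **p)
        if self.model_id == "lightgbm":
            from lightgbm import LGBMClassifier
            p.setdefault("verbose", -1)
            return LGBMClassifier(random_state=self.seed, **p)
        if self.model_id == "logreg":
            p.setdefault("max_iter", 2000)
            return LogisticRegression(random_state=self.seed, **p)
        if self.model_id == "svm":
            p.setdefault("probability", True)
            return SVC(random_state=self.seed, **p)
        if self.model_id == "knn":
            return KNeighborsClassifier(**p)
        raise ModelingError(self.model_id)


def default_model_specs(seed: int = 0) -> List[ModelSpec]:
    return [ModelSpec(m, seed=seed) for m in MODEL_IDS]


@dataclass
class CVResult:
    model_id: str
    fold_f1: List[float]
    fold_auroc: List[float]

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def std_f1(self) -> float:
        return float(np.std(self.fold_f1))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def std_auroc(self) -> float:
        return float(np.std(self.fold_auroc))


def _design(data: pd.DataFrame) -> pd.DataFrame:
    cols = numeric_feature_columns(data)
    if not cols:
        raise ModelingError("no numeric feature columns found")
    return data[cols]


def _binary_labels(data: pd.DataFrame) -> np.ndarray:
    return (data[LABEL_COL] == PD).to_numpy(dtype=int)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted one half (Mann–Whitney rank formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ModelingError("AUROC undefined with a single class")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cross_validate(
    train: pd.DataFrame,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> List[CVResult]:
    """Paired stratified k-fold CV; per-model F1 and AUROC per fold."""
    specs = list(specs) if specs is not None else default_model_specs(seed)
    X = _design(train).to_numpy(dtype=float)
    y = _binary_labels(train)
    if min(np.bincount(y, minlength=2)) < n_folds:
        raise ModelingError("each class needs at least one row per fold")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    results: List[CVResult] = []
    for spec in specs:
        f1s, aucs = [], []
        for tr_idx, va_idx in folds:
            model = spec.build()
            model.fit(X[tr_idx], y[tr_idx])
            scores = model.predict_proba(X[va_idx])[:, 1]
            pred = (scores >= 0.5).astype(int)
            f1s.append(float(f1_score(y[va_idx], pred, zero_division=0)))
            aucs.append(auroc(scores, y[va_idx]))
        results.append(CVResult(spec.model_id, f1s, aucs))
    return results


def select_top(results: Sequence[CVResult], k: int = 3,
               specs: Sequence[ModelSpec] | None = None) -> List[ModelSpec]:
    """Top-k models by mean F1; ties broken by mean AUROC, then id."""
    if not results:
        raise ModelingError("no CV results to select from")
    if k > len(results):
        raise ModelingError(f"k={k} exceeds the {len(results)} evaluated models")
    ordered = sorted(results, key=lambda r: (-r.mean_f1, -r.mean_auroc, r.model_id))
    by_id = {s.model_id: s for s in (specs or [])}
    return [by_id.get(r.model_id, ModelSpec(r.model_id)) for r in ordered[:k]]


def fit_predict(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    cohort: Sequence[Participant],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Fit on the training partition, score the held-out test rows.

    Group attributes in the returned prediction table are carried from
    the cohort record, never from the model inputs.
    """
    feat_cols = numeric_feature_columns(train)
    missing = [c for c in feat_cols if c not in test.columns]
    extra = [c for c in numeric_feature_columns(test) if c not in feat_cols]
    if missing or extra:
        raise ModelingError(
            f"train/test schema mismatch; missing in test: {missing}, "
            f"unexpected in test: {extra}"
        )
    y = _binary_labels(train)
    if len(np.unique(y)) < 2:
        raise ModelingError("training data contain a single class")
    model = spec.build()
    model.fit(train[feat_cols].to_numpy(dtype=float), y)
    scores = model.predict_proba(test[feat_cols].to_numpy(dtype=float))[:, 1]

    by_id = {p.id: p for p in cohort}
    rows = []
    for pid, label, score in zip(test[ID_COL], test[LABEL_COL], scores):
        p = by_id[pid]
        rows.append({
            "participant_id": pid,
            "label": label,
            "score": float(score),
            "predicted": PD if score >= threshold else "non-PD",
            "sex": p.sex,
            "race_binary": p.race_binary,
            "device": p.device,
            "hand": p.hand,
        })
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
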