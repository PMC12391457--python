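"""Train/test split, scaling and the two resampling schemes.

The preprocessing chain mirrors a leakage-safe reading of the study
protocol: stratified 70/30 split first, then (on the training partition
only) random with-replacement resampling of the Non-White non-PD
subgroup toward parity with the White non-PD subgroup, min–max scaling
of numeric features fitted on training rows, synthetic minority
over-sampling (SMOTE) to balance the diagnostic classes, and one-hot
encoding of categoricals fitted on training rows.  Linux rows are
excluded before class balancing, matching the protocol's exclusion of
the eight-participant Linux group during up-sampling.

Every synthetic SMOTE row is a convex combination
``x + u * (x_nn - x)``, ``u in (0, 1)``, of a minority row and one of
its k nearest minority neighbours (Euclidean distance on the scaled
numeric columns); non-numeric columns are copied from the seed row.
A ``provenance`` column tracks original vs. resampled vs. synthetic
rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .cohort import NON_PD, PD, Participant

LABEL_COL = "label"
ID_COL = "participant_id"
PROVENANCE_COL = "provenance"
GROUP_COLS = ("sex", "race_binary", "device", "hand")
_NON_FEATURE = {ID_COL, LABEL_COL, PROVENANCE_COL}


class PreprocessingError(ValueError):
    pass


def attach_labels(features: pd.DataFrame, cohort: List[Participant]) -> pd.DataFrame:
    """Join the diagnostic label onto a feature table by participant id."""
    labels = {p.id: p.label for p in cohort}
    out = features.copy()
    out[LABEL_COL] = out[ID_COL].map(labels)
    if out[LABEL_COL].isna().any():
        missing = out.loc[out[LABEL_COL].isna(), ID_COL].tolist()
        raise PreprocessingError(f"no label for participants {missing}")
    return out


@dataclass
class SplitSpec:
    train_fraction: float = 0.7
    stratify_on: str = LABEL_COL
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise PreprocessingError("train_fraction must be in (0, 1)")


def split(data: pd.DataFrame, spec: SplitSpec | None = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split; deterministic given ``spec.seed``."""
    spec = spec or SplitSpec()
    spec.validate()
    strat = data[spec.stratify_on]
    counts = strat.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise PreprocessingError("each class needs at least 2 rows to split")
    train, test = train_test_split(
        data, train_size=spec.train_fraction, stratify=strat,
        random_state=spec.seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def numeric_feature_columns(data: pd.DataFrame) -> List[str]:
    return [
        c for c in data.columns
        if c not in _NON_FEATURE and pd.api.types.is_numeric_dtype(data[c])
    ]


def categorical_feature_columns(data: pd.DataFrame) -> List[str]:
    return [
        c for c in data.columns
        if c not in _NON_FEATURE and not pd.api.types.is_numeric_dtype(data[c])
    ]


def drop_sparse_rows(data: pd.DataFrame, max_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Remove rows with more than the allowed fraction of missing features."""
    cols = numeric_feature_columns(data)
    if not cols:
        return data
    frac = data[cols].isna().mean(axis=1)
    return data.loc[frac <= max_missing_fraction].reset_index(drop=True)


class MinMaxPreprocessor:
    """Median imputation + min–max scaling + optional one-hot encoding,
    all fitted on the training partition only.

    Scaled training columns lie in [0, 1]; test values transformed with
    the training min/max may fall outside.  A constant column maps to 0.
    """

    def __init__(self, encode_categoricals: bool = True):
        self.encode_categoricals = encode_categoricals

    def get_params(self, deep: bool = True) -> Dict[str, object]:
        return {"encode_categoricals": self.encode_categoricals}

    def set_params(self, **params) -> "MinMaxPreprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, train: pd.DataFrame) -> "MinMaxPreprocessor":
        if len(train) == 0:
            raise PreprocessingError("cannot fit preprocessor on empty training data")
        self.numeric_cols_ = numeric_feature_columns(train)
        self.categorical_cols_ = (
            categorical_feature_columns(train) if self.encode_categoricals else []
        )
        self.medians_ = train[self.numeric_cols_].median()
        self.mins_ = train[self.numeric_cols_].fillna(self.medians_).min()
        self.maxs_ = train[self.numeric_cols_].fillna(self.medians_).max()
        self.categories_ = {
            c: sorted(train[c].dropna().unique()) for c in self.categorical_cols_
        }
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        filled = out[self.numeric_cols_].fillna(self.medians_)
        span = (self.maxs_ - self.mins_).replace(0, 1.0)  # constant column -> 0
        out[self.numeric_cols_] = (filled - self.mins_) / span
        for col in self.categorical_cols_:
            for value in self.categories_[col]:
                out[f"{col}_{value}"] = (data[col] == value).astype(float)
            out = out.drop(columns=[col])
        return out

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


def fit_transform(
    train: pd.DataFrame, test: pd.DataFrame, encode_categoricals: bool = True
) -> Tuple[pd.DataFrame, pd.DataFrame, MinMaxPreprocessor]:
    """Fit on train, transform both; the scaler never sees test rows."""
    prep = MinMaxPreprocessor(encode_categoricals=encode_categoricals)
    return prep.fit_transform(train), prep.transform(test), prep


def one_hot_encode(
    train: pd.DataFrame, test: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One-hot encode categorical feature columns; categories learned on
    the training partition only."""
    cols = categorical_feature_columns(train)
    out_train, out_test = train.copy(), test.copy()
    for col in cols:
        for value in sorted(train[col].dropna().unique()):
            out_train[f"{col}_{value}"] = (train[col] == value).astype(float)
            out_test[f"{col}_{value}"] = (test[col] == value).astype(float)
        out_train = out_train.drop(columns=[col])
        out_test = out_test.drop(columns=[col])
    return out_train, out_test


class SmoteUpsampler:
    """Class balancing by synthetic minority over-sampling.

    ``fit_resample`` interpolates new minority rows between each seed
    row and one of its ``k_neighbors`` nearest minority neighbours.
    """

    def __init__(self, k_neighbors: int = 5, seed: int = 0,
                 exclude_devices: Tuple[str, ...] = ("Linux",)):
        self.k_neighbors = k_neighbors
        self.seed = seed
        self.exclude_devices = exclude_devices

    def get_params(self, deep: bool = True) -> Dict[str, object]:
        return {"k_neighbors": self.k_neighbors, "seed": self.seed,
                "exclude_devices": self.exclude_devices}

    def set_params(self, **params) -> "SmoteUpsampler":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_resample(self, data: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed)
        out = data.copy()
        if PROVENANCE_COL not in out.columns:
            out[PROVENANCE_COL] = "original"
        if self.exclude_devices:
            out = _drop_excluded_devices(out, self.exclude_devices)

        counts = out[LABEL_COL].value_counts()
        if len(counts) < 2:
            raise PreprocessingError("both classes required for SMOTE")
        minority = counts.idxmin()
        n_needed = int(counts.max() - counts.min())
        if n_needed == 0:
            return out.reset_index(drop=True)

        minority_rows = out[out[LABEL_COL] == minority].reset_index(drop=True)
        if len(minority_rows) <= self.k_neighbors:
            raise PreprocessingError(
                f"minority class has {len(minority_rows)} rows, needs more than "
                f"k_neighbors={self.k_neighbors}; use a smaller k"
            )
        num_cols = numeric_feature_columns(out)
        X = minority_rows[num_cols].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise PreprocessingError("impute missing values before SMOTE")
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(X)
        _, idx = nn.kneighbors(X)

        new_rows = []
        for j in range(n_needed):
            i = int(rng.integers(len(minority_rows)))
            neighbor = int(idx[i][1 + rng.integers(self.k_neighbors)])
            u = rng.uniform()
            vec = X[i] + u * (X[neighbor] - X[i])
            row = minority_rows.iloc[i].copy()
            row[num_cols] = vec
            row[ID_COL] = f"{minority_rows.iloc[i][ID_COL]}_smote{j}"
            row[PROVENANCE_COL] = "smote"
            new_rows.append(row)
        return pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)


def _drop_excluded_devices(data: pd.DataFrame, devices: Tuple[str, ...]) -> pd.DataFrame:
    if "device" in data.columns:
        return data[~data["device"].isin(devices)].reset_index(drop=True)
    drop = pd.Series(False, index=data.index)
    for d in devices:
        col = f"device_{d}"
        if col in data.columns:
            drop |= data[col] == 1.0
    return data[~drop].reset_index(drop=True)


def smote_upsample(
    data: pd.DataFrame, k_neighbors: int = 5, seed: int = 0,
    exclude_devices: Tuple[str, ...] = ("Linux",),
) -> pd.DataFrame:
    """Balance class counts by SMOTE; Linux rows are removed first."""
    return SmoteUpsampler(k_neighbors, seed, exclude_devices).fit_resample(data)


def race_upsample(
    data: pd.DataFrame, seed: int = 0, parity_ratio: float = 1.0,
    target_status: str = NON_PD,
) -> pd.DataFrame:
    """Resample Non-White rows of ``target_status`` with replacement
    toward ``parity_ratio`` times the corresponding White subgroup size.

    Added rows are exact copies flagged in the provenance column; all
    other rows are untouched.
    """
    if "race_binary" not in data.columns:
        raise PreprocessingError("race_upsample needs a race_binary column")
    if target_status not in (PD, NON_PD):
        raise PreprocessingError(f"unknown target_status {target_status!r}")
    out = data.copy()
    if PROVENANCE_COL not in out.columns:
        out[PROVENANCE_COL] = "original"

    sub = out[(out["race_binary"] == "Non-White") & (out[LABEL_COL] == target_status)]
    ref = out[(out["race_binary"] == "White") & (out[LABEL_COL] == target_status)]
    if len(sub) == 0:
        raise PreprocessingError(f"empty Non-White {target_status} subgroup")
    target = int(round(parity_ratio * len(ref)))
    n_add = target - len(sub)
    if n_add <= 0:
        return out
    rng = np.random.default_rng(seed)
    picks = rng.integers(len(sub), size=n_add)
    added = sub.iloc[picks].copy()
    added[PROVENANCE_COL] = "resampled"
    return pd.concat([out, added], ignore_index=True)
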