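"""Group fairness audit: performance and fairness metrics with a
group-balanced bootstrap.

Performance metrics (precision, recall/sensitivity, specificity, F1,
accuracy, AUROC) are computed per protected-attribute group; fairness is
summarised by

* disparate impact  DI = [(TP_u+FP_u)/N_u] / [(TP_p+FP_p)/N_p],
* equal opportunity EO = TPR_u / TPR_p,
* equalized odds    EOdds = max(|TPR_u-TPR_p|, |FPR_u-FPR_p|)
  (the literal signed max of the raw differences is available via
  ``mode="signed"``),

with u/p the unprivileged/privileged groups.  DI = EO = 1 and EOdds = 0
denote parity.  Default privilege assignments: male over female, White
over Non-White, Mac over Windows, right- over left-handed.

Error bars come from a balanced bootstrap: each of B replicates draws m
rows with replacement from each group (m = the smaller group size by
default), recomputes every metric, and the report carries the mean and
standard deviation across replicates.  Replicates where a metric is
undefined (zero denominator, single-class draw) contribute missing
values, which are counted and excluded from the summaries.

Significance flags use the percentile bootstrap interval of the
unprivileged-minus-privileged difference: a metric is flagged when the
(alpha/2, 1-alpha/2) interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import PD
from .modeling import auroc as _auroc
from .modeling import ModelingError
from .preprocessing import LABEL_COL, numeric_feature_columns

ATTRIBUTES = ("sex", "race", "device", "hand")
_ATTR_COLUMN = {"sex": "sex", "race": "race_binary", "device": "device",
                "hand": "hand"}

PERFORMANCE_METRICS = ("f1", "sensitivity", "specificity", "precision",
                       "accuracy", "auroc")
FAIRNESS_METRICS = ("disparate_impact", "equal_opportunity", "equalized_odds")


class FairnessError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def default_privilege_map() -> Dict[str, Tuple[str, str]]:
    """attribute -> (privileged value, unprivileged value)."""
    return {
        "sex": ("male", "female"),
        "race": ("White", "Non-White"),
        "device": ("Mac", "Windows"),
        "hand": ("right", "left"),
    }


def confusion_counts(preds: pd.DataFrame) -> ConfusionCounts:
    y = (preds["label"] == PD).to_numpy()
    yhat = (preds["predicted"] == PD).to_numpy()
    return ConfusionCounts(
        tp=int((y & yhat).sum()),
        fp=int((~y & yhat).sum()),
        tn=int((~y & ~yhat).sum()),
        fn=int((y & ~yhat).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def performance_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """Precision, recall, specificity, F1 and accuracy from a confusion
    table; zero-denominator metrics are NaN, never silently 0."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = np.nan
    else:
        f1 = 2 * recall * precision / (recall + precision)
    return {
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "specificity": specificity,
        "f1": f1,
        "accuracy": _ratio(c.tp + c.tn, c.total),
    }


def _split_groups(
    preds: pd.DataFrame, attribute: str,
    privilege: Dict[str, Tuple[str, str]] | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(unprivileged rows, privileged rows); other values are dropped."""
    privilege = privilege or default_privilege_map()
    if attribute not in privilege:
        raise FairnessError(f"unknown attribute {attribute!r}")
    col = _ATTR_COLUMN[attribute]
    priv_value, unpriv_value = privilege[attribute]
    unpriv = preds[preds[col] == unpriv_value]
    priv = preds[preds[col] == priv_value]
    if len(unpriv) == 0 or len(priv) == 0:
        raise FairnessError(
            f"empty group for attribute {attribute!r} "
            f"({unpriv_value}: {len(unpriv)}, {priv_value}: {len(priv)})"
        )
    return unpriv, priv


def _pos_rate(preds: pd.DataFrame) -> float:
    c = confusion_counts(preds)
    return _ratio(c.tp + c.fp, c.total)


def disparate_impact(
    preds: pd.DataFrame, attribute: str,
    privilege: Dict[str, Tuple[str, str]] | None = None,
) -> float:
    """Ratio of positive-prediction rates, unprivileged over privileged."""
    unpriv, priv = _split_groups(preds, attribute, privilege)
    rate_p = _pos_rate(priv)
    if not rate_p or np.isnan(rate_p):
        return np.nan
    return _pos_rate(unpriv) / rate_p


def equal_opportunity(
    preds: pd.DataFrame, attribute: str,
    privilege: Dict[str, Tuple[str, str]] | None = None,
) -> float:
    """Ratio of true-positive rates, unprivileged over privileged."""
    unpriv, priv = _split_groups(preds, attribute, privilege)
    tpr_u = performance_metrics(confusion_counts(unpriv))["sensitivity"]
    tpr_p = performance_metrics(confusion_counts(priv))["sensitivity"]
    if np.isnan(tpr_u) or np.isnan(tpr_p) or tpr_p == 0:
        return np.nan
    return tpr_u / tpr_p


def equalized_odds(
    preds: pd.DataFrame, attribute: str,
    privilege: Dict[str, Tuple[str, str]] | None = None,
    mode: str = "absolute",
) -> float:
    """Worst-case TPR/FPR gap between groups.

    ``mode="absolute"`` (default): max of the absolute differences, so 0
    iff both rate pairs are equal.  ``mode="signed"``: the literal
    max(TPR_u-TPR_p, FPR_u-FPR_p).
    """
    if mode not in ("absolute", "signed"):
        raise FairnessError(f"unknown equalized-odds mode {mode!r}")
    unpriv, priv = _split_groups(preds, attribute, privilege)
    mu = performance_metrics(confusion_counts(unpriv))
    mp = performance_metrics(confusion_counts(priv))
    tpr_u, tpr_p = mu["sensitivity"], mp["sensitivity"]
    fpr_u = 1.0 - mu["specificity"]
    fpr_p = 1.0 - mp["specificity"]
    if any(np.isnan(v) for v in (tpr_u, tpr_p, fpr_u, fpr_p)):
        return np.nan
    if mode == "signed":
        return max(tpr_u - tpr_p, fpr_u - fpr_p)
    return max(abs(tpr_u - tpr_p), abs(fpr_u - fpr_p))


def _group_metrics(rows: pd.DataFrame) -> Dict[str, float]:
    out = performance_metrics(confusion_counts(rows))
    y = (rows["label"] == PD).to_numpy(dtype=int)
    try:
        out["auroc"] = _auroc(rows["score"].to_numpy(), y)
    except ModelingError:
        out["auroc"] = np.nan
    return out


@dataclass
class BootstrapResult:
    """Replicate-level metrics from the group-balanced bootstrap."""

    attribute: str
    n_replicates: int
    draw_size: int
    unpriv: Dict[str, np.ndarray]    # metric -> replicate values
    priv: Dict[str, np.ndarray]
    fairness: Dict[str, np.ndarray]  # DI / EO / EOdds replicate values

    def summary(self) -> Dict[str, Dict[str, float]]:
        out: Dict[str, Dict[str, float]] = {}
        for side, metrics in (("unprivileged", self.unpriv),
                              ("privileged", self.priv),
                              ("fairness", self.fairness)):
            for name, vals in metrics.items():
                valid = vals[np.isfinite(vals)]
                out[f"{side}.{name}"] = {
                    "mean": float(valid.mean()) if len(valid) else np.nan,
                    "std": float(valid.std()) if len(valid) else np.nan,
                    "n_undefined": int(len(vals) - len(valid)),
                }
        return out

    def fairness_ci(self, metric: str, alpha: float = 0.05) -> Tuple[float, float]:
        vals = self.fairness[metric]
        valid = vals[np.isfinite(vals)]
        if len(valid) < 2:
            return (np.nan, np.nan)
        lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)


def bootstrap_group_metrics(
    preds: pd.DataFrame,
    attribute: str,
    privilege: Dict[str, Tuple[str, str]] | None = None,
    B: int = 100,
    m: Optional[int] = None,
    seed: int = 0,
    eodds_mode: str = "absolute",
) -> BootstrapResult:
    """B balanced-bootstrap replicates of all group and fairness metrics.

    Each replicate draws ``m`` rows with replacement from each group
    (default: the smaller group's size) and recomputes everything on the
    drawn rows.  Deterministic given ``seed``.
    """
    unpriv_rows, priv_rows = _split_groups(preds, attribute, privilege)
    if m is None:
        m = min(len(unpriv_rows), len(priv_rows))
    rng = np.random.default_rng(seed)

    names = list(PERFORMANCE_METRICS)
    u_acc = {n: np.empty(B) for n in names}
    p_acc = {n: np.empty(B) for n in names}
    f_acc = {n: np.empty(B) for n in FAIRNESS_METRICS}

    for b in range(B):
        u = unpriv_rows.iloc[rng.integers(len(unpriv_rows), size=m)]
        p = priv_rows.iloc[rng.integers(len(priv_rows), size=m)]
        mu, mp = _group_metrics(u), _group_metrics(p)
        for n in names:
            u_acc[n][b] = mu[n]
            p_acc[n][b] = mp[n]
        rate_p = _pos_rate(p)
        f_acc["disparate_impact"][b] = (
            _pos_rate(u) / rate_p if rate_p and not np.isnan(rate_p) else np.nan
        )
        tpr_u, tpr_p = mu["sensitivity"], mp["sensitivity"]
        f_acc["equal_opportunity"][b] = (
            tpr_u / tpr_p
            if not (np.isnan(tpr_u) or np.isnan(tpr_p) or tpr_p == 0)
            else np.nan
        )
        fpr_u, fpr_p = 1 - mu["specificity"], 1 - mp["specificity"]
        if any(np.isnan(v) for v in (tpr_u, tpr_p, fpr_u, fpr_p)):
            f_acc["equalized_odds"][b] = np.nan
        elif eodds_mode == "signed":
            f_acc["equalized_odds"][b] = max(tpr_u - tpr_p, fpr_u - fpr_p)
        else:
            f_acc["equalized_odds"][b] = max(abs(tpr_u - tpr_p), abs(fpr_u - fpr_p))

    return BootstrapResult(attribute=attribute, n_replicates=B, draw_size=m,
                           unpriv=u_acc, priv=p_acc, fairness=f_acc)


def significance_flags(
    result: BootstrapResult,
    alpha: float = 0.05,
    metrics: Sequence[str] = ("f1", "sensitivity", "specificity", "precision"),
    min_valid: int = 30,
) -> Dict[str, Optional[bool]]:
    """Flag metrics whose bootstrap CI of the group difference
    (unprivileged minus privileged) excludes zero.

    ``None`` marks metrics with too few valid replicates to decide.
    """
    flags: Dict[str, Optional[bool]] = {}
    for name in metrics:
        diff = result.unpriv[name] - result.priv[name]
        valid = diff[np.isfinite(diff)]
        if len(valid) < min_valid:
            flags[name] = None
            continue
        lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
        flags[name] = bool(lo > 0 or hi < 0)
    return flags


def stratified_importance(
    data: pd.DataFrame,
    subgroup: Optional[Dict[str, str]] = None,
    seed: int = 0,
    top_k: Optional[int] = None,
) -> List[Tuple[str, float]]:
    """Impurity-based random-forest feature importance, refit on the
    subgroup's rows only; importances are normalised to sum to 1.

    ``subgroup`` filters rows by column equality, e.g.
    ``{"device": "Mac"}``; ``None`` gives the global ranking.
    """
    rows = data
    if subgroup:
        for col, value in subgroup.items():
            rows = rows[rows[col] == value]
    y = (rows[LABEL_COL] == PD).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise FairnessError("subgroup must contain both classes")
    cols = numeric_feature_columns(rows)
    model = RandomForestClassifier(random_state=seed)
    model.fit(rows[cols].to_numpy(dtype=float), y)
    imp = model.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    ranked = sorted(zip(cols, imp.tolist()), key=lambda t: -t[1])
    return ranked[:top_k] if top_k else ranked


def audit_predictions(
    preds: pd.DataFrame,
    privilege: Dict[str, Tuple[str, str]] | None = None,
    attributes: Sequence[str] = ATTRIBUTES,
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    eodds_mode: str = "absolute",
) -> Dict[str, dict]:
    """Full per-attribute fairness report for one prediction table."""
    report: Dict[str, dict] = {}
    for i, attribute in enumerate(attributes):
        result = bootstrap_group_metrics(
            preds, attribute, privilege, B=B, seed=seed + i,
            eodds_mode=eodds_mode,
        )
        report[attribute] = {
            "point": {
                "disparate_impact": disparate_impact(preds, attribute, privilege),
                "equal_opportunity": equal_opportunity(preds, attribute, privilege),
                "equalized_odds": equalized_odds(preds, attribute, privilege,
                                                 mode=eodds_mode),
            },
            "bootstrap": result.summary(),
            "fairness_ci": {
                m: result.fairness_ci(m, alpha) for m in FAIRNESS_METRICS
            },
            "significance_flags": significance_flags(result, alpha),
            "n_replicates": B,
            "draw_size": result.draw_size,
        }
    return report


def report_to_markdown(report: Dict[str, dict], title: str = "Fairness audit") -> str:
    lines = [f"# {title}", ""]
    for attribute, block in report.items():
        lines += [f"## {attribute}", ""]
        lines.append(
            f"Bootstrap: {block['n_replicates']} replicates, "
            f"{block['draw_size']} rows drawn per group."
        )
        lines += ["", "| metric | mean | std |", "|---|---|---|"]
        for key, stats in block["bootstrap"].items():
            lines.append(
                f"| {key} | {stats['mean']:.3f} | {stats['std']:.3f} |"
            )
        lines.append("")
        flags = block["significance_flags"]
        flagged = [m for m, f in flags.items() if f]
        lines.append(
            "Significant group differences: "
            + (", ".join(flagged) if flagged else "none")
        )
        lines.append("")
    return "\n".join(lines)
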