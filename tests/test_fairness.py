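from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from motorfair.cohort import NON_PD, PD
from motorfair.fairness import (
    FairnessError,
    audit_predictions,
    bootstrap_group_metrics,
    confusion_counts,
    default_privilege_map,
    disparate_impact,
    equal_opportunity,
    equalized_odds,
    performance_metrics,
    report_to_markdown,
    significance_flags,
    stratified_importance,
)


def random_pred_table(rng, n=None):
    n = n or int(rng.integers(8, 100))
    return pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "label": rng.choice([PD, NON_PD], size=n),
        "score": rng.uniform(size=n),
        "predicted": rng.choice([PD, NON_PD], size=n),
        "sex": rng.choice(["male", "female"], size=n),
        "race_binary": rng.choice(["White", "Non-White"], size=n),
        "device": rng.choice(["Windows", "Mac"], size=n),
        "hand": rng.choice(["right", "left"], size=n),
    })


def oracle_counts(rows):
    tp = fp = tn = fn = 0
    for _, r in rows.iterrows():
        if r["label"] == PD and r["predicted"] == PD:
            tp += 1
        elif r["label"] != PD and r["predicted"] == PD:
            fp += 1
        elif r["label"] != PD and r["predicted"] != PD:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def frac(num, den):
    return Fraction(num, den) if den > 0 else None


def oracle_fairness(rows, col, priv_value, unpriv_value):
    """Row-enumeration oracle for DI / EO / EOdds as exact fractions."""
    u = rows[rows[col] == unpriv_value]
    p = rows[rows[col] == priv_value]
    if len(u) == 0 or len(p) == 0:
        return None
    tp_u, fp_u, tn_u, fn_u = oracle_counts(u)
    tp_p, fp_p, tn_p, fn_p = oracle_counts(p)
    rate_u = frac(tp_u + fp_u, len(u))
    rate_p = frac(tp_p + fp_p, len(p))
    di = (rate_u / rate_p
          if rate_u is not None and rate_p not in (None, 0) else None)
    tpr_u = frac(tp_u, tp_u + fn_u)
    tpr_p = frac(tp_p, tp_p + fn_p)
    eo = (tpr_u / tpr_p
          if tpr_u is not None and tpr_p not in (None, 0) else None)
    fpr_u = frac(fp_u, fp_u + tn_u)
    fpr_p = frac(fp_p, fp_p + tn_p)
    if None in (tpr_u, tpr_p, fpr_u, fpr_p):
        eodds_abs = eodds_signed = None
    else:
        eodds_abs = max(abs(tpr_u - tpr_p), abs(fpr_u - fpr_p))
        eodds_signed = max(tpr_u - tpr_p, fpr_u - fpr_p)
    return di, eo, eodds_abs, eodds_signed


def check(expected, actual):
    if expected is None:
        assert np.isnan(actual)
    else:
        assert abs(float(expected) - actual) <= 1e-12


class TestMetricOracle:
    """Criterion: 500 random prediction tables, implementation matches a
    row-enumeration brute-force oracle to 1e-12 (exact fractions)."""

    def test_500_random_tables(self, rng):
        attrs = default_privilege_map()
        checked = 0
        for i in range(500):
            preds = random_pred_table(rng)
            for attr, (priv, unpriv) in attrs.items():
                oracle = oracle_fairness(
                    preds, {"race": "race_binary"}.get(attr, attr), priv, unpriv)
                if oracle is None:
                    with pytest.raises(FairnessError):
                        disparate_impact(preds, attr)
                    continue
                di, eo, eabs, esigned = oracle
                check(di, disparate_impact(preds, attr))
                check(eo, equal_opportunity(preds, attr))
                check(eabs, equalized_odds(preds, attr))
                check(esigned, equalized_odds(preds, attr, mode="signed"))
                checked += 1
        assert checked > 1500  # nearly all tables have non-empty groups

    def test_performance_metrics_oracle(self, rng):
        for _ in range(100):
            preds = random_pred_table(rng)
            tp, fp, tn, fn = oracle_counts(preds)
            c = confusion_counts(preds)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            m = performance_metrics(c)
            check(frac(tp, tp + fn), m["sensitivity"])
            check(frac(tn, tn + fp), m["specificity"])
            check(frac(tp, tp + fp), m["precision"])
            check(frac(tp + tn, tp + fp + tn + fn), m["accuracy"])
            prec, rec = frac(tp, tp + fp), frac(tp, tp + fn)
            if prec is None or rec is None or prec + rec == 0:
                assert np.isnan(m["f1"])
            else:
                check(2 * prec * rec / (prec + rec), m["f1"])


class TestParityValues:
    def test_identical_groups_are_parity(self, rng):
        half = random_pred_table(rng, n=40)
        half["device"] = "Mac"
        other = half.copy()
        other["device"] = "Windows"
        preds = pd.concat([half, other], ignore_index=True)
        if (preds["predicted"] == PD).sum() == 0:
            preds.loc[0, "predicted"] = PD
            preds.loc[40, "predicted"] = PD
        assert disparate_impact(preds, "device") == pytest.approx(1.0)
        assert equalized_odds(preds, "device") == pytest.approx(0.0)

    def test_unknown_attribute(self, rng):
        with pytest.raises(FairnessError, match="attribute"):
            disparate_impact(random_pred_table(rng), "age")

    def test_unknown_eodds_mode(self, rng):
        with pytest.raises(FairnessError, match="mode"):
            equalized_odds(random_pred_table(rng), "sex", mode="both")


class TestBootstrap:
    def test_deterministic(self, rng):
        preds = random_pred_table(rng, n=80)
        a = bootstrap_group_metrics(preds, "sex", B=50, seed=3)
        b = bootstrap_group_metrics(preds, "sex", B=50, seed=3)
        for k in a.fairness:
            np.testing.assert_array_equal(a.fairness[k], b.fairness[k])

    def test_draw_size_default_min_group(self, rng):
        preds = random_pred_table(rng, n=80)
        res = bootstrap_group_metrics(preds, "device", B=10)
        n_min = min((preds["device"] == "Mac").sum(),
                    (preds["device"] == "Windows").sum())
        assert res.draw_size == n_min

    def test_explicit_draw_size(self, rng):
        preds = random_pred_table(rng, n=80)
        res = bootstrap_group_metrics(preds, "device", B=10, m=50)
        assert res.draw_size == 50

    def test_summary_shape(self, rng):
        preds = random_pred_table(rng, n=80)
        s = bootstrap_group_metrics(preds, "hand", B=25).summary()
        assert "unprivileged.f1" in s and "fairness.disparate_impact" in s
        for stats in s.values():
            assert set(stats) == {"mean", "std", "n_undefined"}

    def test_ci_ordering(self, rng):
        preds = random_pred_table(rng, n=80)
        res = bootstrap_group_metrics(preds, "sex", B=100)
        lo, hi = res.fairness_ci("disparate_impact")
        assert lo <= hi


class TestSignificanceFlags:
    def test_forced_difference_flagged(self, rng):
        # unprivileged predictions are always wrong, privileged always right
        n = 120
        labels = rng.choice([PD, NON_PD], size=n)
        sex = np.array(["female"] * (n // 2) + ["male"] * (n // 2))
        predicted = np.where(
            sex == "male", labels,
            np.where(labels == PD, NON_PD, PD))
        preds = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "label": labels, "score": rng.uniform(size=n),
            "predicted": predicted, "sex": sex,
            "race_binary": "White", "device": "Mac", "hand": "right",
        })
        res = bootstrap_group_metrics(preds, "sex", B=100, seed=0)
        flags = significance_flags(res)
        assert flags["sensitivity"] is True

    def test_too_few_valid_replicates_is_none(self, rng):
        preds = random_pred_table(rng, n=40)
        res = bootstrap_group_metrics(preds, "sex", B=10, seed=0)
        flags = significance_flags(res, min_valid=30)
        # only 10 replicates exist, so every flag is undecidable
        assert all(v is None for v in flags.values())


class TestAuditReport:
    def test_report_structure_and_markdown(self, rng):
        preds = random_pred_table(rng, n=90)
        report = audit_predictions(preds, B=20, seed=0)
        assert set(report) == {"sex", "race", "device", "hand"}
        block = report["device"]
        assert set(block["point"]) == {
            "disparate_impact", "equal_opportunity", "equalized_odds"}
        assert block["n_replicates"] == 20
        md = report_to_markdown(report)
        assert "## device" in md and "| metric |" in md


class TestStratifiedImportance:
    def test_normalised_and_filtered(self, small_features, small_cohort):
        from motorfair.preprocessing import attach_labels
        data = attach_labels(small_features, small_cohort)
        ranked = stratified_importance(data, subgroup={"device": "Mac"},
                                       top_k=10)
        assert len(ranked) == 10
        total = sum(v for _, v in stratified_importance(data))
        assert total == pytest.approx(1.0)
        with pytest.raises(FairnessError, match="both classes"):
            stratified_importance(data, subgroup={"device": "nonexistent"})
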