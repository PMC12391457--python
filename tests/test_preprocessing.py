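import numpy as np
import pandas as pd
import pytest

from motorfair.cohort import NON_PD, PD, CohortConfig, generate_cohort
from motorfair.preprocessing import (
    MinMaxPreprocessor,
    PreprocessingError,
    SmoteUpsampler,
    SplitSpec,
    attach_labels,
    drop_sparse_rows,
    fit_transform,
    numeric_feature_columns,
    one_hot_encode,
    race_upsample,
    smote_upsample,
    split,
)


def toy_frame(n=40, seed=0, with_groups=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(n)],
        "a": rng.normal(size=n),
        "b": rng.normal(5, 2, size=n),
        "label": [PD if i < n // 4 else NON_PD for i in range(n)],
    })
    if with_groups:
        df["device"] = ["Linux" if i % 10 == 0 else
                        ("Mac" if i % 2 else "Windows") for i in range(n)]
        df["race_binary"] = ["Non-White" if i % 5 == 0 else "White"
                             for i in range(n)]
    return df


class TestAttachLabels:
    def test_joins_by_id(self, small_features, small_cohort):
        data = attach_labels(small_features, small_cohort)
        by_id = {p.id: p.label for p in small_cohort}
        assert (data["label"] == data["participant_id"].map(by_id)).all()

    def test_missing_participant_raises(self, small_features, small_cohort):
        with pytest.raises(PreprocessingError, match="no label"):
            attach_labels(small_features, small_cohort[:-1])


class TestSplit:
    def test_default_cohort_sizes(self, default_cohort):
        frame = pd.DataFrame({
            "participant_id": [p.id for p in default_cohort],
            "x": np.arange(len(default_cohort), dtype=float),
            "label": [p.label for p in default_cohort],
        })
        train, test = split(frame)
        assert len(train) == 175 and len(test) == 76

    def test_stratification(self, default_cohort):
        frame = pd.DataFrame({
            "participant_id": [p.id for p in default_cohort],
            "x": np.zeros(len(default_cohort)),
            "label": [p.label for p in default_cohort],
        })
        train, test = split(frame)
        frac_train = (train["label"] == PD).mean()
        frac_test = (test["label"] == PD).mean()
        assert abs(frac_train - frac_test) < 0.02

    def test_deterministic(self):
        df = toy_frame()
        a1, b1 = split(df, SplitSpec(seed=3))
        a2, b2 = split(df, SplitSpec(seed=3))
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_invalid_fraction(self):
        with pytest.raises(PreprocessingError):
            split(toy_frame(), SplitSpec(train_fraction=1.5))

    def test_single_class_rejected(self):
        df = toy_frame()
        df["label"] = PD
        with pytest.raises(PreprocessingError, match="class"):
            split(df)


class TestMinMax:
    def test_train_in_unit_interval(self):
        train, test = toy_frame(seed=1), toy_frame(seed=2)
        tr, te, prep = fit_transform(train, test, encode_categoricals=False)
        for c in ("a", "b"):
            assert tr[c].min() == pytest.approx(0.0)
            assert tr[c].max() == pytest.approx(1.0)
        # test transformed with train min/max, may exceed [0, 1]
        assert list(te.columns) == list(tr.columns)

    def test_median_imputation_from_train_only(self):
        train = toy_frame(seed=1)
        test = toy_frame(seed=2)
        train.loc[0, "a"] = np.nan
        test.loc[0, "a"] = np.nan
        tr, te, prep = fit_transform(train, test, encode_categoricals=False)
        assert np.isfinite(tr["a"]).all() and np.isfinite(te["a"]).all()
        med = train["a"].median()
        expected = (med - prep.mins_["a"]) / (prep.maxs_["a"] - prep.mins_["a"])
        assert te.loc[0, "a"] == pytest.approx(expected)

    def test_constant_column_maps_to_zero(self):
        train = toy_frame(seed=1)
        train["c"] = 3.0
        test = toy_frame(seed=2)
        test["c"] = 5.0
        tr, te, _ = fit_transform(train, test, encode_categoricals=False)
        assert (tr["c"] == 0.0).all()

    def test_label_and_id_untouched(self):
        train, test = toy_frame(seed=1), toy_frame(seed=2)
        tr, _, _ = fit_transform(train, test, encode_categoricals=False)
        assert (tr["label"] == train["label"]).all()
        assert (tr["participant_id"] == train["participant_id"]).all()

    def test_estimator_interface(self):
        prep = MinMaxPreprocessor(encode_categoricals=False)
        assert prep.get_params() == {"encode_categoricals": False}
        prep.set_params(encode_categoricals=True)
        assert prep.encode_categoricals is True
        with pytest.raises(PreprocessingError, match="empty"):
            prep.fit(toy_frame().iloc[:0])


class TestOneHot:
    def test_categories_from_train(self):
        train, test = toy_frame(seed=1), toy_frame(seed=2)
        tr, te = one_hot_encode(train, test)
        assert "device" not in tr.columns
        assert {"device_Linux", "device_Mac", "device_Windows"} <= set(tr.columns)
        assert set(tr.columns) == set(te.columns)
        assert tr["device_Mac"].isin([0.0, 1.0]).all()


class TestSmote:
    def test_balances_classes_and_convexity(self):
        df = toy_frame(n=60)
        out = smote_upsample(df, k_neighbors=3, seed=0)
        counts = out["label"].value_counts()
        assert counts[PD] == counts[NON_PD]
        # Linux rows removed before balancing
        assert not (out["device"] == "Linux").any()
        # componentwise interval check: every synthetic point lies inside
        # the componentwise range of the original minority rows
        originals = df[(df["label"] == PD) & (df["device"] != "Linux")]
        synth = out[out["provenance"] == "smote"]
        assert len(synth) > 0
        for c in ("a", "b"):
            assert synth[c].min() >= originals[c].min() - 1e-12
            assert synth[c].max() <= originals[c].max() + 1e-12

    def test_synthetic_on_segment_between_two_parents(self):
        # with k=1 each synthetic point sits on the segment between a seed
        # row and its single nearest neighbour
        df = toy_frame(n=60, with_groups=False)
        out = SmoteUpsampler(k_neighbors=1, seed=0,
                             exclude_devices=()).fit_resample(df)
        originals = df[df["label"] == PD][["a", "b"]].to_numpy()
        for _, row in out[out["provenance"] == "smote"].iterrows():
            p = np.array([row["a"], row["b"]])
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    ab = originals[j] - originals[i]
                    denom = ab @ ab
                    if denom == 0:
                        continue
                    u = (p - originals[i]) @ ab / denom
                    proj = originals[i] + u * ab
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(p, proj, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_small_minority_errors_with_advice(self):
        df = toy_frame(n=16)  # 4 minority rows <= k=5
        with pytest.raises(PreprocessingError, match="smaller k"):
            smote_upsample(df)

    def test_nan_rejected(self):
        df = toy_frame(n=60)
        df.loc[2, "a"] = np.nan
        with pytest.raises(PreprocessingError, match="impute"):
            smote_upsample(df, k_neighbors=3)

    def test_already_balanced_is_noop(self):
        df = toy_frame(n=40, with_groups=False)
        df["label"] = [PD] * 20 + [NON_PD] * 20
        out = SmoteUpsampler(k_neighbors=3, exclude_devices=()).fit_resample(df)
        assert len(out) == 40

    def test_deterministic(self):
        df = toy_frame(n=60)
        a = smote_upsample(df, k_neighbors=3, seed=9)
        b = smote_upsample(df, k_neighbors=3, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestRaceUpsample:
    def test_parity_reached(self):
        df = toy_frame(n=60)
        out = race_upsample(df, seed=0)
        sub = out[(out["race_binary"] == "Non-White") & (out["label"] == NON_PD)]
        ref = out[(out["race_binary"] == "White") & (out["label"] == NON_PD)]
        assert len(sub) == len(ref)
        added = out[out["provenance"] == "resampled"]
        # added rows are exact copies of existing Non-White non-PD rows
        pool = df[(df["race_binary"] == "Non-White") & (df["label"] == NON_PD)]
        assert added["participant_id"].isin(pool["participant_id"]).all()

    def test_ratio_below_one(self):
        df = toy_frame(n=60)
        out = race_upsample(df, seed=0, parity_ratio=0.5)
        sub = out[(out["race_binary"] == "Non-White") & (out["label"] == NON_PD)]
        ref = out[(out["race_binary"] == "White") & (out["label"] == NON_PD)]
        assert len(sub) == round(0.5 * len(ref))

    def test_requires_race_column(self):
        with pytest.raises(PreprocessingError, match="race_binary"):
            race_upsample(toy_frame(with_groups=False))


class TestSparseRows:
    def test_drops_above_threshold(self):
        df = toy_frame(n=10, with_groups=False)
        df.loc[0, ["a", "b"]] = np.nan  # 100% missing
        out = drop_sparse_rows(df, max_missing_fraction=0.2)
        assert len(out) == 9
        assert "P000" not in out["participant_id"].tolist()

    def test_numeric_feature_columns_exclude_meta(self):
        df = toy_frame()
        assert numeric_feature_columns(df) == ["a", "b"]
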