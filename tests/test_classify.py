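"""IQR filtering, grouped splitting, the forest and its evaluation."""

import numpy as np
import pandas as pd
import pytest

from phenofuse.calibration import CLASS_LABELS
from phenofuse.classify import (
    SplitError,
    build_sample_table,
    confusion_from_predictions,
    dominant_class_map,
    evaluate,
    evaluate_matrix,
    feature_columns,
    group_split,
    iqr_filter,
    stratified_group_cv,
    train_classifier,
)
from phenofuse.harmonize import harmonize_landscape
from phenofuse.reference import REFERENCE_DATASETS, load_reference_matrix


def toy_table(rng, n_fields=10, cells_per_field=8, classes=("soybean", "fallow")):
    rows = []
    for fid in range(n_fields):
        label = classes[fid % len(classes)]
        center = 0.8 if label == "soybean" else 0.3
        for _ in range(cells_per_field):
            rows.append({"f0": rng.normal(center, 0.05), "f1": rng.normal(-center, 0.05),
                         "label": label, "field_id": fid})
    return pd.DataFrame(rows)


class TestIqrFilter:
    def base(self, values, label="soybean"):
        return pd.DataFrame({"x": values, "label": label, "field_id": 0})

    def test_1234_bounds_and_no_removal(self):
        table = self.base([1.0, 2.0, 3.0, 4.0])
        out, removed, bounds = iqr_filter(table, ["x"])
        assert bounds.q1.loc["soybean", "x"] == pytest.approx(1.75)
        assert bounds.q3.loc["soybean", "x"] == pytest.approx(3.25)
        assert bounds.lower.loc["soybean", "x"] == pytest.approx(-0.5)
        assert bounds.upper.loc["soybean", "x"] == pytest.approx(5.5)
        assert len(out) == 4 and removed["soybean"] == 0

    def test_outlier_row_removed_exactly(self):
        table = self.base([1.0, 2.0, 3.0, 4.0, 100.0])
        out, removed, _ = iqr_filter(table, ["x"])
        assert removed["soybean"] == 1
        assert 100.0 not in out["x"].values and len(out) == 4

    def test_identical_values_collapse_bounds(self):
        table = self.base([2.0, 2.0, 2.0, 2.0, 3.0])
        out, removed, _ = iqr_filter(table, ["x"])
        assert removed["soybean"] == 1 and (out["x"] == 2.0).all()

    def test_small_class_skipped_with_warning(self):
        table = self.base([1.0, 2.0, 100.0])
        with pytest.warns(UserWarning, match="skipped"):
            out, removed, _ = iqr_filter(table, ["x"])
        assert len(out) == 3

    def test_bounds_computed_per_class(self):
        table = pd.concat([
            self.base([1.0, 2.0, 3.0, 4.0], "soybean"),
            self.base([10.0, 20.0, 30.0, 40.0], "fallow"),
        ])
        out, removed, _ = iqr_filter(table, ["x"])
        assert len(out) == 8  # 10-40 are outliers only under soybean's bounds


class TestGroupSplit:
    def test_equal_fields_split_in_half(self, rng):
        table = toy_table(rng, n_fields=10, classes=("soybean",))
        train, test = group_split(table, 0.5, rng_seed=0)
        assert test["field_id"].nunique() == 5
        assert train["field_id"].nunique() == 5

    def test_no_field_on_both_sides(self, rng):
        table = toy_table(rng, n_fields=17, cells_per_field=5)
        train, test = group_split(table, 0.5, rng_seed=3)
        assert not set(train["field_id"]) & set(test["field_id"])
        assert len(train) + len(test) == len(table)

    def test_realized_fraction_near_target(self, rng):
        table = toy_table(rng, n_fields=40, cells_per_field=12)
        _, test = group_split(table, 0.5, rng_seed=1)
        assert abs(len(test) / len(table) - 0.5) < 0.05

    def test_single_field_class_rejected(self, rng):
        table = toy_table(rng, n_fields=3, classes=("soybean", "fallow", "buckwheat"))
        with pytest.raises(SplitError, match="single field"):
            group_split(table, 0.5, rng_seed=0)


class TestForest:
    def test_separable_classes_reach_perfect_training_accuracy(self, rng):
        table = toy_table(rng)
        model = train_classifier(table, ["f0", "f1"], rng_seed=0)
        assert (model.predict(table[["f0", "f1"]].to_numpy()) == table["label"]).all()

    def test_same_seed_reproduces_predictions(self, rng):
        table = toy_table(rng, n_fields=14)
        X = table[["f0", "f1"]].to_numpy()
        a = train_classifier(table, ["f0", "f1"], rng_seed=5).predict(X)
        b = train_classifier(table, ["f0", "f1"], rng_seed=5).predict(X)
        assert (a == b).all()

    def test_permuted_labels_give_chance_accuracy(self, rng):
        n = 500
        table = pd.DataFrame({
            "f0": rng.normal(size=2 * n), "f1": rng.normal(size=2 * n),
            "label": rng.permutation(np.repeat(list(CLASS_LABELS), 2 * n // 5)),
            "field_id": np.arange(2 * n),
        })
        model = train_classifier(table.iloc[:n], ["f0", "f1"], rng_seed=0)
        acc = (model.predict(table.iloc[n:][["f0", "f1"]].to_numpy())
               == table.iloc[n:]["label"]).mean()
        assert abs(acc - 0.2) < 0.08  # five balanced classes, no signal

    def test_single_class_training_rejected(self, rng):
        table = toy_table(rng, classes=("soybean",))
        with pytest.raises(SplitError):
            train_classifier(table, ["f0", "f1"])


class TestEvaluate:
    def test_identity_matrix_is_perfect(self):
        m = pd.DataFrame(np.diag([10, 20, 30, 40, 50]),
                         index=CLASS_LABELS, columns=CLASS_LABELS)
        rep = evaluate_matrix(m)
        assert rep.oa == 100.0
        assert all(v == 1.0 for v in rep.f1.values())
        assert rep.f1_mean == 1.0

    @pytest.mark.parametrize("name", REFERENCE_DATASETS)
    def test_row_and_column_sums_relate_to_tp_fp_fn(self, name):
        m = load_reference_matrix(name)
        arr = m.to_numpy(float)
        tp = np.diag(arr)
        fp = arr.sum(axis=0) - tp
        fn = arr.sum(axis=1) - tp
        assert np.allclose(tp + fn, arr.sum(axis=1))
        assert np.allclose(tp + fp, arr.sum(axis=0))
        assert (arr >= 0).all()

    def test_metrics_match_pair_counting_brute_force(self, rng):
        actual = rng.choice(CLASS_LABELS, 300)
        pred = rng.choice(CLASS_LABELS, 300)
        rep = evaluate_matrix(confusion_from_predictions(actual, pred))
        assert rep.oa == pytest.approx(100 * np.mean(actual == pred))
        for c in CLASS_LABELS:
            tp = np.sum((actual == c) & (pred == c))
            fp = np.sum((actual != c) & (pred == c))
            fn = np.sum((actual == c) & (pred != c))
            assert rep.f1[c] == pytest.approx(tp / (tp + (fp + fn) / 2))

    def test_absent_class_excluded_with_warning(self):
        m = pd.DataFrame(np.diag([5, 5, 0, 5, 5]), index=CLASS_LABELS, columns=CLASS_LABELS)
        with pytest.warns(UserWarning, match="buckwheat"):
            rep = evaluate_matrix(m)
        assert "buckwheat" not in rep.f1 and len(rep.f1) == 4

    def test_summary_prints_oa_row(self):
        rep = evaluate_matrix(load_reference_matrix("multisensor"))
        assert "OA, % 94" in rep.summary()


@pytest.mark.filterwarnings("ignore::UserWarning")  # tiny folds lack classes
class TestCrossValidation:
    def test_nine_fields_three_classes_one_field_per_fold(self, rng):
        table = toy_table(rng, n_fields=9, cells_per_field=6,
                          classes=("soybean", "fallow", "buckwheat"))
        rep = stratified_group_cv(table, ["f0", "f1"], k=3, rng_seed=0, apply_iqr=False)
        assert len(rep.folds) == 3
        seen = []
        for fold in rep.folds:
            assert fold.matrix.to_numpy().sum() == 18  # 3 fields x 6 cells
        assert rep.matrix.to_numpy().sum() == len(table)

    def test_every_field_tested_exactly_once(self, rng):
        table = toy_table(rng, n_fields=12, cells_per_field=4)
        rep = stratified_group_cv(table, ["f0", "f1"], k=3, rng_seed=1, apply_iqr=False)
        assert rep.matrix.to_numpy().sum() == len(table)

    def test_infeasible_stratification_names_class(self, rng):
        table = toy_table(rng, n_fields=4, classes=("soybean", "fallow"))
        with pytest.raises(SplitError, match="fewer than 3"):
            stratified_group_cv(table, ["f0", "f1"], k=3)


class TestDominantClassMap:
    def test_modal_class_wins(self):
        pred = pd.DataFrame({"field_id": [1, 1, 1], "predicted": ["soybean", "soybean", "fallow"]})
        assert dominant_class_map(pred)[1] == "soybean"

    def test_tie_broken_by_probability_then_order(self):
        pred = pd.DataFrame({"field_id": [1, 1], "predicted": ["fallow", "soybean"]})
        proba = pd.DataFrame({"soybean": [0.9, 0.6], "fallow": [0.1, 0.4]}, index=pred.index)
        assert dominant_class_map(pred, proba)[1] == "soybean"
        # equal mass: canonical order decides
        proba2 = pd.DataFrame({"soybean": [0.5, 0.5], "fallow": [0.5, 0.5]}, index=pred.index)
        assert dominant_class_map(pred, proba2)[1] == "soybean"

    def test_field_majority_does_not_hurt_on_average(self, small_landscape):
        """Averaged over 10 split seeds, field-level majority voting
        smooths away isolated cell errors rather than adding new ones."""
        cube = harmonize_landscape(small_landscape)
        table = build_sample_table(cube)
        feats = feature_columns(table, ("sentinel", "landsat", "meteor"))
        diffs = []
        for seed in range(10):
            train, test = group_split(table, 0.5, rng_seed=seed)
            model = train_classifier(train, feats, rng_seed=seed)
            pred = model.predict(test[feats].to_numpy())
            cell_oa = np.mean(pred == test["label"])
            fmap = dominant_class_map(
                pd.DataFrame({"field_id": test["field_id"].values, "predicted": pred})
            )
            truth = test.groupby("field_id")["label"].first()
            field_oa = np.mean(fmap.loc[truth.index] == truth)
            diffs.append(field_oa - cell_oa)
        assert np.mean(diffs) >= 0.0


def test_sample_table_has_no_missing_features(small_landscape):
    cube = harmonize_landscape(small_landscape)
    table = build_sample_table(cube)
    feats = feature_columns(table)
    assert len(feats) == 78  # 3 sensors x 26 weeks
    assert table[feats].notna().all().all()
    assert table.groupby("field_id")["label"].nunique().max() == 1
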