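"""Random-forest crop/fallow classification with grouped evaluation.

Samples are grid cells; the feature vector is the cell's 26-week NDVI
series per sensor (26 features single-sensor, 78 for the three-sensor
set), optionally with the field-level NDVImax/DOYmax indicators
appended.  Fields are the grouping unit everywhere: train/test splits
and cross-validation folds never place cells of one field on both
sides, which prevents spatial leakage between neighbouring cells.

Training data are filtered per class with the interquartile-range rule
(a row is dropped when any feature leaves [Q1 - 1.5 IQR, Q3 + 1.5 IQR]
for its class), the forest uses 50 trees, and accuracy is reported as
a confusion matrix (rows = actual, columns = predicted), overall
accuracy OA = trace/total, per-class F1 = TP / (TP + (FP + FN)/2) and
their unweighted mean F1mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold

from .calibration import CLASS_LABELS
from .harmonize import WeeklyCube

DEFAULT_N_TREES = 50
DEFAULT_TEST_FRACTION = 0.5
DEFAULT_CV_FOLDS = 3

META_COLUMNS = ("label", "field_id")


class SplitError(ValueError):
    pass


def feature_columns(table: pd.DataFrame, sensors=None) -> list:
    """Feature column names for a sensor subset (None = all present)."""
    cols = [c for c in table.columns if c not in META_COLUMNS]
    if sensors is None:
        return cols
    keep = []
    for s in sensors:
        keep.extend(c for c in cols if c.startswith(f"{s}_"))
    return keep


def build_sample_table(cube: WeeklyCube, sensors=None) -> pd.DataFrame:
    """One row per labeled cell with complete features.

    Columns ``<sensor>_w00 .. _w25`` hold the weekly NDVI values; rows
    with any missing sensor-week value are dropped (the cube flags
    them), so the table satisfies the no-missing-features contract.
    """
    sensors = list(cube.layers if sensors is None else sensors)
    labeled = cube.label_grid >= 0
    complete = np.ones(cube.grid.shape, bool)
    for s in sensors:
        complete &= np.all(np.isfinite(cube.layers[s]), axis=0)
    keep = labeled & complete

    data = {}
    for s in sensors:
        block = cube.layers[s][:, keep]  # (26, n)
        for k in range(block.shape[0]):
            data[f"{s}_w{k:02d}"] = block[k]
    table = pd.DataFrame(data)
    table["label"] = np.asarray(CLASS_LABELS, object)[cube.label_grid[keep]]
    table["field_id"] = cube.field_id_grid[keep]
    return table


@dataclass
class IqrBounds:
    """Per-class, per-feature outlier bounds from the IQR rule."""

    q1: pd.DataFrame  # class x feature
    q3: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame


def iqr_filter(train: pd.DataFrame, features=None, factor: float = 1.5):
    """Remove per-class outliers from the training partition.

    Quartiles use linear interpolation between order statistics (the
    "type 7" rule).  A row is removed when any of its features falls
    outside its class's [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Classes with
    fewer than 4 rows are passed through unfiltered with a warning.

    Returns ``(filtered, removed_per_class, bounds)``.
    """
    features = feature_columns(train) if features is None else list(features)
    keep = pd.Series(True, index=train.index)
    q1_rows, q3_rows, classes = [], [], []
    removed = {}
    for label, sub in train.groupby("label", sort=False):
        if len(sub) < 4:
            warnings.warn(
                f"class {label!r} has {len(sub)} rows (< 4): IQR filtering skipped"
            )
            removed[label] = 0
            continue
        X = sub[features]
        q1 = X.quantile(0.25)
        q3 = X.quantile(0.75)
        iqr = q3 - q1
        lo, hi = q1 - factor * iqr, q3 + factor * iqr
        ok = ((X >= lo) & (X <= hi)).all(axis=1)
        keep.loc[sub.index] = ok
        removed[label] = int((~ok).sum())
        classes.append(label)
        q1_rows.append(q1)
        q3_rows.append(q3)
    if classes:
        q1df = pd.DataFrame(q1_rows, index=classes)
        q3df = pd.DataFrame(q3_rows, index=classes)
        bounds = IqrBounds(q1df, q3df, q1df - factor * (q3df - q1df), q3df + factor * (q3df - q1df))
    else:
        bounds = None
    return train[keep], removed, bounds


def group_split(table: pd.DataFrame, test_fraction: float = DEFAULT_TEST_FRACTION, rng_seed: int = 0):
    """Field-grouped, class-stratified train/test split.

    Whole fields go to one side.  Within each class the (shuffled)
    fields are assigned to the test side until its row count reaches
    the target fraction of the class, which preserves per-class area
    ratios; a class with a single field cannot be split and raises
    :class:`SplitError`.
    """
    rng = np.random.default_rng(rng_seed)
    test_fields = []
    for label, sub in table.groupby("label", sort=False):
        sizes = sub.groupby("field_id").size()
        if len(sizes) < 2:
            raise SplitError(f"class {label!r} has a single field; cannot split")
        order = rng.permutation(sizes.index.to_numpy())
        target = test_fraction * sizes.sum()
        chosen, got = [], 0
        for fid in order:
            if got >= target or len(chosen) == len(sizes) - 1:
                break  # target reached, or one field must stay in train
            new = got + sizes[fid]
            # skip a field that would overshoot more than it helps
            if got > 0 and (new - target) > (target - got):
                continue
            chosen.append(fid)
            got = new
        test_fields.extend(chosen)
    mask = table["field_id"].isin(test_fields)
    return table[~mask], table[mask]


def train_classifier(
    train: pd.DataFrame, features=None, n_trees: int = DEFAULT_N_TREES, rng_seed: int = 0
) -> RandomForestClassifier:
    """Fit the random forest (bagged axis-aligned trees, majority vote)."""
    features = feature_columns(train) if features is None else list(features)
    if train["label"].nunique() < 2:
        raise SplitError("training data contain a single class")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=int(rng_seed))
    model.fit(train[features].to_numpy(), train["label"].to_numpy())
    model.feature_names_ = list(features)
    return model


@dataclass
class EvaluationReport:
    """Confusion matrix plus the derived accuracy metrics."""

    matrix: pd.DataFrame  # rows = actual, columns = predicted
    oa: float  # percent
    f1: dict  # class -> F1 in [0, 1]
    f1_mean: float
    folds: list = field(default_factory=list)  # per-fold reports (CV)

    def rounded(self):
        """(OA to whole percent, F1 to 2 decimals) as printed in reports."""
        return round(self.oa), {c: round(v, 2) for c, v in self.f1.items()}

    def summary(self) -> str:
        m = self.matrix.copy()
        m["F1"] = [f"{self.f1[c]:.2f}" if c in self.f1 else "-" for c in m.index]
        lines = [m.to_string()]
        lines.append(f"OA, % {round(self.oa)}")
        lines.append(f"F1mean {self.f1_mean:.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "matrix": {r: self.matrix.loc[r].to_dict() for r in self.matrix.index},
            "oa_percent": self.oa,
            "f1": dict(self.f1),
            "f1_mean": self.f1_mean,
        }


def confusion_from_predictions(actual, predicted, labels=CLASS_LABELS) -> pd.DataFrame:
    actual = pd.Categorical(actual, categories=labels)
    predicted = pd.Categorical(predicted, categories=labels)
    return pd.crosstab(actual, predicted, dropna=False).reindex(
        index=labels, columns=labels, fill_value=0
    )


def evaluate_matrix(matrix: pd.DataFrame) -> EvaluationReport:
    """OA, per-class F1 and F1mean from a confusion matrix.

    Classes absent from both the rows and the columns (no actual and no
    predicted sample) are excluded from F1mean with a warning.
    """
    m = matrix.to_numpy(float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    total = m.sum()
    oa = 100.0 * tp.sum() / total if total else float("nan")
    f1 = {}
    for i, label in enumerate(matrix.index):
        support = m[i].sum() + m[:, i].sum()
        if support == 0:
            warnings.warn(f"class {label!r} absent from the evaluation; excluded from F1mean")
            continue
        denom = tp[i] + (fp[i] + fn[i]) / 2.0
        f1[label] = float(tp[i] / denom) if denom else 0.0
    f1_mean = float(np.mean(list(f1.values()))) if f1 else float("nan")
    return EvaluationReport(matrix=matrix, oa=float(oa), f1=f1, f1_mean=f1_mean)


def evaluate(model, test: pd.DataFrame, features=None) -> EvaluationReport:
    """Evaluate a fitted model on a grouped test partition."""
    if not len(test):
        raise ValueError("empty test set")
    features = getattr(model, "feature_names_", None) if features is None else list(features)
    pred = model.predict(test[features].to_numpy())
    return evaluate_matrix(confusion_from_predictions(test["label"], pred))


def stratified_group_cv(
    table: pd.DataFrame,
    features=None,
    k: int = DEFAULT_CV_FOLDS,
    rng_seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    apply_iqr: bool = True,
) -> EvaluationReport:
    """k-fold stratified group cross-validation (fields never split).

    Every field lands in the test fold exactly once; per-fold class
    proportions approximately follow the table's.  Returns the pooled
    report (summed confusion matrix) with per-fold reports attached.
    """
    features = feature_columns(table) if features is None else list(features)
    counts = table.groupby("label")["field_id"].nunique()
    short = counts[counts < k]
    if len(short):
        raise SplitError(
            f"stratification infeasible with k={k}: class(es) "
            f"{list(short.index)} have fewer than {k} fields"
        )
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=int(rng_seed))
    y = table["label"].to_numpy()
    groups = table["field_id"].to_numpy()
    folds = []
    pooled = None
    for f, (tr, te) in enumerate(splitter.split(table, y, groups)):
        train, test = table.iloc[tr], table.iloc[te]
        if apply_iqr:
            train, _, _ = iqr_filter(train, features)
        model = train_classifier(train, features, n_trees=n_trees, rng_seed=rng_seed + f)
        rep = evaluate(model, test, features)
        folds.append(rep)
        pooled = rep.matrix if pooled is None else pooled + rep.matrix
    out = evaluate_matrix(pooled)
    out.folds = folds
    return out


def run_classification(
    table: pd.DataFrame,
    sensors=None,
    rng_seed: int = 0,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    n_trees: int = DEFAULT_N_TREES,
) -> EvaluationReport:
    """Grouped 50/50 split -> IQR filter -> forest -> evaluation."""
    features = feature_columns(table, sensors)
    train, test = group_split(table, test_fraction, rng_seed)
    train, _, _ = iqr_filter(train, features)
    model = train_classifier(train, features, n_trees=n_trees, rng_seed=rng_seed)
    return evaluate(model, test, features)


def dominant_class_map(predictions: pd.DataFrame, proba: pd.DataFrame | None = None) -> pd.Series:
    """Field-level class map from per-cell predictions.

    ``predictions`` needs columns ``field_id`` and ``predicted``.  Ties
    in the per-field modal class are broken by total predicted
    probability mass (when ``proba`` is given, indexed like
    ``predictions`` with one column per class), then by canonical class
    order.  Returns a Series field_id -> class label.
    """
    order = {c: i for i, c in enumerate(CLASS_LABELS)}
    out = {}
    for fid, sub in predictions.groupby("field_id"):
        counts = sub["predicted"].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1 and proba is not None:
            mass = proba.loc[sub.index, top].sum()
            top = mass[mass == mass.max()].index.tolist()
        out[fid] = min(top, key=lambda c: order.get(c, len(order)))
    return pd.Series(out, name="class").rename_axis("field_id")
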