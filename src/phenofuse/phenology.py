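"""Field- and class-level phenology metrics and year comparisons.

The two primary indicators are NDVImax, the maximum of a field's mean
NDVI series over the season, and DOYmax, the day of year on which it
occurs.  Classes with an early and a late seasonal maximum (mown
grasses, late-sown buckwheat) are additionally summarised by two
maxima on either side of a configurable split day (default DOY 210,
which separates the reported late-June first maxima from the
August-September second maxima).

Class summaries report the mean with a t-based 95 % half-width and the
coefficient of variation (sd/mean in percent) for both indicators;
year-to-year differences are tested with one-way ANOVA plus Tukey HSD
pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .harmonize import WeeklyCube
from .timeseries import InsufficientDataError, WEEKLY_ANCHORS

DEFAULT_SPLIT_DOY = 210


@dataclass
class PhenologySummary:
    field_id: int
    class_label: str
    ndvi_max: float
    doy_max: int
    first_max: tuple | None = None  # (value, doy) before the split
    second_max: tuple | None = None  # (value, doy) from the split on


@dataclass
class ClassSummary:
    class_label: str
    n_fields: int
    ndvi_max_mean: float
    ndvi_max_halfwidth: float
    ndvi_max_cv: float  # percent
    doy_max_mean: float
    doy_max_halfwidth: float
    doy_max_cv: float  # percent

    def row(self) -> dict:
        return {
            "class": self.class_label,
            "n": self.n_fields,
            "NDVImax_mean": self.ndvi_max_mean,
            "NDVImax_halfwidth": self.ndvi_max_halfwidth,
            "VAR_NDVI": self.ndvi_max_cv,
            "DOYmax_mean": self.doy_max_mean,
            "DOYmax_halfwidth": self.doy_max_halfwidth,
            "VAR_DOY": self.doy_max_cv,
        }


@dataclass
class GroupComparison:
    levels: tuple
    f_statistic: float
    p_anova: float
    pairwise_p: dict  # (level_i, level_j) -> Tukey HSD p-value
    degenerate: bool = False  # all values identical within groups


def field_mean_series(cube: WeeklyCube, field_id: int, sensor: str) -> np.ndarray:
    """Unweighted per-week mean over a field's cells (NaN-aware)."""
    cells = cube.field_id_grid == field_id
    if not cells.any():
        raise InsufficientDataError(f"field {field_id} covers no cell")
    block = cube.layers[sensor][:, cells]  # (26, n_cells)
    with np.errstate(invalid="ignore"):
        return np.nanmean(block, axis=1)


def extract_max(series, anchors=None) -> tuple[float, int]:
    """(NDVImax, DOYmax) over the weekly grid; ties take the earliest anchor."""
    series = np.asarray(series, float)
    anchors = WEEKLY_ANCHORS if anchors is None else np.asarray(anchors)
    good = np.isfinite(series)
    if not good.any():
        raise InsufficientDataError("series is all-missing")
    best = np.nanmax(series)
    idx = int(np.flatnonzero(good & (series == best))[0])
    return float(best), int(anchors[idx])


def extract_two_maxima(series, anchors=None, split_doy: int = DEFAULT_SPLIT_DOY):
    """Early/late maxima on either side of ``split_doy``.

    Returns ``(first, second)`` where each is ``(value, doy)`` or None
    when that side of the season holds no valid value.
    """
    series = np.asarray(series, float)
    anchors = WEEKLY_ANCHORS if anchors is None else np.asarray(anchors)
    early = anchors < split_doy
    out = []
    for side in (early, ~early):
        vals = series[side]
        if side.any() and np.isfinite(vals).any():
            out.append(extract_max(vals, anchors[side]))
        else:
            out.append(None)
    return tuple(out)


def summarize_field(cube, field_obj_or_id, sensor, split_doy=None) -> PhenologySummary:
    """Full phenology summary of one field from the weekly cube."""
    fid = getattr(field_obj_or_id, "field_id", field_obj_or_id)
    label = getattr(field_obj_or_id, "class_label", "")
    series = field_mean_series(cube, fid, sensor)
    v, d = extract_max(series, cube.anchors)
    first = second = None
    if split_doy is not None:
        first, second = extract_two_maxima(series, cube.anchors, split_doy)
    return PhenologySummary(fid, label, v, d, first_max=first, second_max=second)


def class_summary(ndvi_max, doy_max, class_label="", confidence=0.95) -> ClassSummary:
    """Mean, t-based half-width and CV of both indicators across fields."""
    v = np.asarray(ndvi_max, float)
    d = np.asarray(doy_max, float)
    n = v.size
    if n < 2 or d.size != n:
        raise InsufficientDataError("class summary needs >= 2 fields")
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)

    def _stats(x):
        m = x.mean()
        sd = x.std(ddof=1)
        half = tcrit * sd / np.sqrt(n)
        cv = 100.0 * sd / m if m != 0 else np.inf
        return m, half, cv

    vm, vh, vc = _stats(v)
    dm, dh, dc = _stats(d)
    return ClassSummary(class_label, n, vm, vh, vc, dm, dh, dc)


def anova_tukey(groups: dict) -> GroupComparison:
    """One-way ANOVA + Tukey HSD over named groups (e.g. years).

    Degenerate input (zero variance everywhere) is flagged and reported
    with an infinite F and p = 0 when the means differ, or F = 0 and
    p = 1 when all values coincide.
    """
    levels = tuple(groups)
    arrays = [np.asarray(groups[k], float) for k in levels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InsufficientDataError("ANOVA needs >= 2 groups of >= 2 values")

    if all(a.std() == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        same = len(set(means)) == 1
        p = 1.0 if same else 0.0
        pairs = {
            (levels[i], levels[j]): (1.0 if arrays[i].mean() == arrays[j].mean() else 0.0)
            for i, j in combinations(range(len(levels)), 2)
        }
        return GroupComparison(levels, 0.0 if same else np.inf, p, pairs, degenerate=True)

    f_stat, p_anova = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairs = {
        (levels[i], levels[j]): float(hsd.pvalue[i, j])
        for i, j in combinations(range(len(levels)), 2)
    }
    return GroupComparison(levels, float(f_stat), float(p_anova), pairs)
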