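"""Phenology indicators, class summaries and year comparisons."""

import numpy as np
import pytest
from scipy import stats

from phenofuse.calibration import DEFAULT_CLASS_MODELS
from phenofuse.harmonize import harmonize_landscape
from phenofuse.phenology import (
    anova_tukey,
    class_summary,
    extract_max,
    extract_two_maxima,
    field_mean_series,
    summarize_field,
)
from phenofuse.synthetic import sample_phenology_curve
from phenofuse.timeseries import (
    InsufficientDataError,
    SEASON_DAYS,
    WEEKLY_ANCHORS,
    weekly_composites,
)


@pytest.fixture(scope="module")
def small_cube(small_landscape):
    return harmonize_landscape(small_landscape)


class TestFieldSeries:
    def test_single_pixel_field_returns_its_series(self, small_cube):
        sizes = [((small_cube.field_id_grid == f).sum(), f)
                 for f in np.unique(small_cube.field_id_grid) if f >= 0]
        _, fid = min(sizes)
        series = field_mean_series(small_cube, fid, "meteor")
        cells = small_cube.field_id_grid == fid
        assert np.allclose(series, small_cube.layers["meteor"][:, cells].mean(axis=1))

    def test_mean_matches_per_week_oracle(self, small_cube):
        fid = int(small_cube.field_id_grid.max())
        series = field_mean_series(small_cube, fid, "sentinel")
        cells = small_cube.field_id_grid == fid
        block = small_cube.layers["sentinel"][:, cells]
        for k in range(26):
            vals = block[k][np.isfinite(block[k])]
            if vals.size:
                assert series[k] == pytest.approx(vals.mean())

    def test_empty_field_rejected(self, small_cube):
        with pytest.raises(InsufficientDataError):
            field_mean_series(small_cube, 10_000, "sentinel")

    def test_invariant_to_pixel_ordering(self, small_cube):
        fid = int(small_cube.field_id_grid.max())
        a = extract_max(field_mean_series(small_cube, fid, "meteor"))
        flipped = small_cube.layers["meteor"][:, ::-1, ::-1]
        cells = small_cube.field_id_grid[::-1, ::-1] == fid
        b = extract_max(np.nanmean(flipped[:, cells], axis=1))
        assert a == pytest.approx(b)


class TestExtractMax:
    def test_monotone_series_peaks_at_last_anchor(self):
        v, d = extract_max(np.linspace(0.1, 0.9, 26))
        assert d == WEEKLY_ANCHORS[-1] and v == pytest.approx(0.9)

    def test_constructed_peak_value_and_anchor(self):
        series = np.full(26, 0.3)
        series[14] = 0.88  # anchor 121 + 14*7 = 219
        assert extract_max(series) == (0.88, 219)

    def test_tie_takes_earliest_anchor(self):
        series = np.full(26, 0.2)
        series[[5, 9]] = 0.7
        assert extract_max(series)[1] == WEEKLY_ANCHORS[5]

    def test_all_missing_rejected(self):
        with pytest.raises(InsufficientDataError):
            extract_max(np.full(26, np.nan))


class TestTwoMaxima:
    def test_simulated_bimodal_peaks_recovered(self):
        curve = sample_phenology_curve(
            DEFAULT_CLASS_MODELS["perennial_grasses"].__class__(
                "perennial_grasses", 0.81, 0.0, 175, 0.0, baseline=0.3,
                curve_family="bimodal_mixture", peak_width_days=20,
                secondary_peak=DEFAULT_CLASS_MODELS["perennial_grasses"].secondary_peak.__class__(
                    0.78, 0.0, 260, 0.0),
            ), 0,
        )
        weekly = weekly_composites(curve(SEASON_DAYS))
        (v1, d1), (v2, d2) = extract_two_maxima(weekly, split_doy=210)
        assert abs(d1 - 175) <= 7 and abs(d2 - 260) <= 7
        assert v1 == pytest.approx(0.81, abs=0.05)
        assert v2 == pytest.approx(0.78, abs=0.05)

    def test_unimodal_early_curve_lacks_second_peak(self):
        series = np.concatenate([np.linspace(0.2, 0.8, 10), np.full(16, np.nan)])
        first, second = extract_two_maxima(series, split_doy=210)
        assert first is not None and second is None

    def test_split_at_season_start_degenerates_to_global_max(self):
        rng = np.random.default_rng(3)
        series = rng.random(26)
        first, second = extract_two_maxima(series, split_doy=121)
        assert first is None
        assert second == extract_max(series)

    def test_summarize_field_carries_both_maxima(self, small_cube, small_landscape):
        grasses = [f for f in small_landscape.fields
                   if f.class_label == "perennial_grasses"
                   and (small_cube.field_id_grid == f.field_id).any()]
        s = summarize_field(small_cube, grasses[0], "meteor", split_doy=210)
        assert s.first_max is not None and s.second_max is not None
        assert s.first_max[1] < s.second_max[1]


class TestClassSummary:
    def test_identical_fields_have_zero_spread(self):
        s = class_summary([0.8] * 5, [200] * 5, "soybean")
        assert s.ndvi_max_halfwidth == 0 and s.ndvi_max_cv == 0
        assert s.doy_max_halfwidth == 0 and s.doy_max_cv == 0

    def test_three_values_match_textbook_formulas(self):
        v = np.array([0.7, 0.8, 0.9])
        d = np.array([200.0, 210.0, 220.0])
        s = class_summary(v, d)
        tcrit = stats.t.ppf(0.975, 2)
        assert s.ndvi_max_mean == pytest.approx(0.8)
        assert s.ndvi_max_halfwidth == pytest.approx(tcrit * v.std(ddof=1) / np.sqrt(3))
        assert s.ndvi_max_cv == pytest.approx(100 * v.std(ddof=1) / 0.8)
        assert s.doy_max_mean == pytest.approx(210.0)

    def test_simulated_cohort_recovers_configured_statistics(self):
        model = DEFAULT_CLASS_MODELS["soybean"]
        rng = np.random.default_rng(6)
        peaks, doys = [], []
        for _ in range(200):
            v = sample_phenology_curve(model, rng.integers(2**31))(SEASON_DAYS)
            peaks.append(v.max())
            doys.append(SEASON_DAYS[np.argmax(v)])
        s = class_summary(peaks, doys, "soybean")
        assert s.ndvi_max_mean == pytest.approx(0.88, abs=0.01)
        assert s.ndvi_max_cv == pytest.approx(4.89, abs=1.0)

    def test_permutation_invariance(self, rng):
        v = rng.random(10)
        d = rng.integers(150, 250, 10).astype(float)
        p = rng.permutation(10)
        a, b = class_summary(v, d), class_summary(v[p], d[p])
        assert a.ndvi_max_mean == b.ndvi_max_mean
        assert a.doy_max_cv == b.doy_max_cv

    def test_single_field_rejected(self):
        with pytest.raises(InsufficientDataError):
            class_summary([0.8], [200])


class TestAnovaTukey:
    def test_null_case_not_significant(self, rng):
        groups = {y: 0.8 + rng.normal(0, 0.05, 30) for y in (2022, 2023, 2024)}
        cmp = anova_tukey(groups)
        assert cmp.p_anova > 0.05
        assert all(p > 0.05 for p in cmp.pairwise_p.values())

    def test_extreme_separation_all_significant(self, rng):
        groups = {k: m + rng.normal(0, 0.01, 10) for k, m in zip("abc", (0.0, 1.0, 2.0))}
        cmp = anova_tukey(groups)
        assert cmp.p_anova < 1e-10
        assert all(p < 1e-6 for p in cmp.pairwise_p.values())

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(0.0, 1.0, 12), rng.normal(0.4, 1.0, 12)
        cmp = anova_tukey({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert cmp.f_statistic == pytest.approx(t**2)

    def test_degenerate_identical_values_flagged(self):
        same = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert same.degenerate and same.p_anova == 1.0
        diff = anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert diff.degenerate and diff.p_anova == 0.0 and np.isinf(diff.f_statistic)

    def test_pairwise_covers_all_level_pairs(self, rng):
        groups = {y: rng.normal(0, 1, 8) for y in (2022, 2023, 2024)}
        cmp = anova_tukey(groups)
        assert set(cmp.pairwise_p) == {(2022, 2023), (2022, 2024), (2023, 2024)}

    def test_tukey_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {y: rng.normal(0.1 * i, 1.0, 15) for i, y in enumerate((2022, 2023, 2024))}
        cmp = anova_tukey(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(values, labels)
        assert np.allclose(sorted(cmp.pairwise_p.values()), sorted(sm.pvalues), atol=1e-6)
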