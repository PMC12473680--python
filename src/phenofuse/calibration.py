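"""Default calibration of the synthetic landscape.

The simulator's defaults emulate the study region the package targets:
five field classes (soybean, grain crops, buckwheat, perennial grasses,
fallow land) observed by three sensors with distinct resolutions and
revisit schedules.  Class seasonal-curve statistics (peak NDVI, its
day-of-year, and their field-to-field spreads) follow the published
field-survey summaries for the region; sensor properties follow the
reported inter-sensor offsets (the 60 m daily-composite sensor reads
~0.06 NDVI lower and peaks ~15 days earlier than the 20/30 m sensors)
and the reported per-scene masked-pixel distributions.

Everything here is a plain data structure that the generator consumes;
all values can be overridden through :class:`LandscapeConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_LABELS = (
    "soybean",
    "grain_crops",
    "buckwheat",
    "perennial_grasses",
    "fallow",
)

#: Overall class area shares (ha-based, three seasons pooled).
CLASS_AREA_PROPORTIONS = {
    "soybean": 20384.08 / 36052.04,
    "grain_crops": 4620.84 / 36052.04,
    "buckwheat": 1422.08 / 36052.04,
    "perennial_grasses": 2623.88 / 36052.04,
    "fallow": 7001.16 / 36052.04,
}


@dataclass(frozen=True)
class SecondaryPeak:
    value_mean: float
    value_sd: float
    doy_mean: float
    doy_sd: float


@dataclass(frozen=True)
class ClassPhenologyModel:
    """Field-to-field distribution of one class's seasonal NDVI curve.

    ``curve_family`` selects the functional form of the truth curve:
    ``fourier`` (same truncated harmonic basis as the gap-filling model,
    so a noiseless closed loop recovers it exactly), ``double_logistic``
    (an out-of-basis alternative for robustness checks) or
    ``bimodal_mixture`` (two Gaussian bumps over a baseline, for classes
    with an early and a late maximum).
    """

    class_label: str
    peak_value_mean: float
    peak_value_sd: float
    peak_doy_mean: float
    peak_doy_sd: float
    baseline: float = 0.25
    sharpness: float = 0.0  # >0 sharper peak, <0 plateau (fourier family)
    curve_family: str = "fourier"
    secondary_peak: SecondaryPeak | None = None
    peak_width_days: float = 30.0  # bump scale (bimodal_mixture family)

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ConfigurationError(f"unknown class label {self.class_label!r}")
        if not 0.0 < self.peak_value_mean <= 1.0:
            raise ConfigurationError("peak_value_mean must lie in (0, 1]")
        if not 121 <= self.peak_doy_mean <= 296:
            raise ConfigurationError("peak_doy_mean must lie in [121, 296]")
        if self.curve_family not in ("fourier", "double_logistic", "bimodal_mixture"):
            raise ConfigurationError(f"unknown curve family {self.curve_family!r}")
        if self.secondary_peak is not None and not (
            self.secondary_peak.doy_mean > self.peak_doy_mean
        ):
            raise ConfigurationError("secondary peak must follow the primary peak")


class ConfigurationError(ValueError):
    pass


#: Default class curve models.  Peak statistics follow the 20 m sensor's
#: field summaries (2022 season; buckwheat uses the later bimodal season,
#: which exercises the two-maximum analysis); sd values are derived from
#: the printed coefficients of variation (sd = mean * VAR / 100).
DEFAULT_CLASS_MODELS = {
    "soybean": ClassPhenologyModel(
        "soybean",
        peak_value_mean=0.88,
        peak_value_sd=0.88 * 0.0489,
        peak_doy_mean=220.8,
        peak_doy_sd=220.8 * 0.0288,
        baseline=0.22,
        sharpness=0.15,
    ),
    "grain_crops": ClassPhenologyModel(
        "grain_crops",
        peak_value_mean=0.77,
        peak_value_sd=0.77 * 0.0509,
        peak_doy_mean=192.0,
        peak_doy_sd=192.0 * 0.1479,
        baseline=0.22,
        sharpness=0.30,  # sharp green-up then post-harvest decline
    ),
    "buckwheat": ClassPhenologyModel(
        "buckwheat",
        peak_value_mean=0.55,
        peak_value_sd=0.05,
        peak_doy_mean=165.0,
        peak_doy_sd=6.0,
        baseline=0.20,
        curve_family="bimodal_mixture",
        peak_width_days=18.0,
        # late-sown main crop: the dominant, later maximum
        secondary_peak=SecondaryPeak(
            value_mean=0.80, value_sd=0.80 * 0.0603, doy_mean=242.8, doy_sd=242.8 * 0.0212
        ),
    ),
    "perennial_grasses": ClassPhenologyModel(
        "perennial_grasses",
        peak_value_mean=0.81,
        peak_value_sd=0.81 * 0.070,
        peak_doy_mean=174.0,
        peak_doy_sd=174.0 * 0.059,
        baseline=0.30,
        curve_family="bimodal_mixture",
        peak_width_days=22.0,
        secondary_peak=SecondaryPeak(
            value_mean=0.78, value_sd=0.78 * 0.120, doy_mean=264.7, doy_sd=264.7 * 0.032
        ),
    ),
    "fallow": ClassPhenologyModel(
        "fallow",
        peak_value_mean=0.84,
        peak_value_sd=0.84 * 0.0578,
        peak_doy_mean=190.9,
        peak_doy_sd=190.9 * 0.0562,
        baseline=0.35,
        sharpness=-0.2,  # plateau-shaped season (must stay > -0.25 for a true peak)
    ),
}

#: Per-scene masked-fraction bin probabilities (<5, 5-20, 20-50, >50 %),
#: 2022-season scene tallies.
SENTINEL_MASK_DIST = (8 / 61, 5 / 61, 11 / 61, 37 / 61)
LANDSAT_MASK_DIST = (2 / 15, 1 / 15, 5 / 15, 7 / 15)


@dataclass(frozen=True)
class SensorModel:
    """Acquisition properties of one sensor."""

    sensor_id: str
    native_resolution_m: float
    schedule: str  # "jitter3" | "period11" | "daily"
    additive_bias: float = 0.0
    peak_shift_days: float = 0.0  # negative = season appears earlier
    noise_sd: float = 0.02
    mask_fraction_distribution: tuple[float, float, float, float] | None = None
    has_quality_layer: bool = True
    emits_reflectance: bool = True  # NIR/RED pair vs ready NDVI composite

    def __post_init__(self):
        if self.mask_fraction_distribution is not None:
            p = np.asarray(self.mask_fraction_distribution, float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError("mask bin probabilities must sum to 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


DEFAULT_SENSORS = {
    "sentinel": SensorModel(
        "sentinel",
        native_resolution_m=20.0,
        schedule="jitter3",  # ~61 scenes per season
        additive_bias=0.0,
        peak_shift_days=0.0,
        noise_sd=0.02,
        mask_fraction_distribution=SENTINEL_MASK_DIST,
    ),
    "landsat": SensorModel(
        "landsat",
        native_resolution_m=30.0,
        schedule="period11",  # ~15 scenes per season
        additive_bias=0.03,
        peak_shift_days=0.0,
        noise_sd=0.02,
        mask_fraction_distribution=LANDSAT_MASK_DIST,
    ),
    "meteor": SensorModel(
        "meteor",
        native_resolution_m=60.0,
        schedule="daily",  # daily composites, DOY 122-269
        additive_bias=-0.06,
        peak_shift_days=-15.0,
        noise_sd=0.015,
        mask_fraction_distribution=None,  # delivered composites, no QA layer
        has_quality_layer=False,
        emits_reflectance=False,
    ),
}

SENSOR_IDS = tuple(DEFAULT_SENSORS)


@dataclass
class LandscapeConfig:
    """Configuration of one synthetic landscape.

    The default geographic extent gives a ~100 x 100 cell grid at the
    60 m common resolution, populated with ~200 rectangular fields.
    ``spatial_sd`` is the within-field pixel-to-pixel NDVI spread (a
    free parameter of the simulator, default 0.02).
    """

    west: float = 135.0
    north: float = 48.60
    size_cells: int = 100  # target-grid cells per side (60 m)
    resolution_m: float = 60.0
    year: int = 2022
    field_size_cells: tuple[int, int] = (4, 10)  # min/max field side, 60 m cells
    field_gap_cells: int = 1
    spatial_sd: float = 0.02
    proportions: dict = field(default_factory=lambda: dict(CLASS_AREA_PROPORTIONS))
    class_models: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MODELS))
    sensors: dict = field(default_factory=lambda: dict(DEFAULT_SENSORS))

    @property
    def bounds(self):
        ext = self.size_cells * self.resolution_m / 111_000.0
        return (self.west, self.north - ext, self.west + ext, self.north)

    def noiseless(self) -> "LandscapeConfig":
        """Copy with all noise, bias and cloud sources switched off."""
        sensors = {
            k: SensorModel(
                s.sensor_id,
                s.native_resolution_m,
                s.schedule,
                additive_bias=0.0,
                peak_shift_days=0.0,
                noise_sd=0.0,
                mask_fraction_distribution=None,
                has_quality_layer=s.has_quality_layer,
                emits_reflectance=s.emits_reflectance,
            )
            for k, s in self.sensors.items()
        }
        return LandscapeConfig(
            west=self.west,
            north=self.north,
            size_cells=self.size_cells,
            resolution_m=self.resolution_m,
            year=self.year,
            field_size_cells=self.field_size_cells,
            field_gap_cells=self.field_gap_cells,
            spatial_sd=0.0,
            proportions=dict(self.proportions),
            class_models=dict(self.class_models),
            sensors=sensors,
        )
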