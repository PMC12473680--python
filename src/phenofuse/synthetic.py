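"""Synthetic multi-sensor landscape and scene-stack generator.

The generator builds a rectangular agricultural landscape of labeled
fields, gives every field a class-specific seasonal NDVI truth curve,
and renders dated scenes for each sensor at its native resolution and
revisit schedule, with sensor bias, observation noise and spatially
coherent cloud occlusion.  Because every downstream quantity (labels,
truth curves, cloud bins) is known, the whole pipeline is testable
without any satellite download.

Scenes are emitted the way the real products arrive: the 20 m sensor as
an NIR/RED reflectance pair plus an SCL-style scene-classification
grid, the 30 m sensor as a reflectance pair plus a QA-integer grid, and
the 60 m sensor as ready daily NDVI composites with no quality layer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import (
    CLASS_LABELS,
    ClassPhenologyModel,
    ConfigurationError,
    LandscapeConfig,
    SensorModel,
)
from .grids import GridSpec, build_target_grid, rasterize_fields
from .masking import CLOUD_BINS, LANDSAT_CLEAR_VALUE
from .timeseries import METEOR_END, METEOR_START, SEASON_END, SEASON_START, W_DEFAULT

BACKGROUND_NDVI = 0.35

# Half-season distance (days) at which a fourier-family curve reaches
# its baseline value.
_BASELINE_DIST = 100.0

# Uniform sampling ranges for the realized masked fraction within each
# drawn bin, kept strictly inside the bin boundaries.
_BIN_FRACTION_RANGES = {
    "<5": (0.0, 0.045),
    "5-20": (0.055, 0.19),
    "20-50": (0.21, 0.49),
    ">50": (0.51, 0.93),
}


def _fourier_curve(peak_value, peak_doy, baseline, sharpness):
    """Truncated-harmonic truth curve with a single maximum.

    Built in the same basis as the gap-filling model (frequency
    ``W_DEFAULT``): f(d) = a0 + c1*cos(w*(d-dp)) + s*c1*cos(2w*(d-dp)).
    c1 and a0 are solved so f(dp) = peak and f(dp +/- 100 d) = baseline.
    """
    w = W_DEFAULT
    s = sharpness
    denom = (1 + s) - (np.cos(w * _BASELINE_DIST) + s * np.cos(2 * w * _BASELINE_DIST))
    c1 = (peak_value - baseline) / denom
    a0 = peak_value - c1 * (1 + s)

    def f(d):
        u = (np.asarray(d, float) - peak_doy) * w
        return np.clip(a0 + c1 * np.cos(u) + s * c1 * np.cos(2 * u), 0.0, 1.0)

    return f


def _bimodal_curve(v1, d1, v2, d2, baseline, width):
    """Two Gaussian bumps over a baseline (early + late maxima)."""

    def f(d):
        d = np.asarray(d, float)
        out = (
            baseline
            + (v1 - baseline) * np.exp(-0.5 * ((d - d1) / width) ** 2)
            + (v2 - baseline) * np.exp(-0.5 * ((d - d2) / width) ** 2)
        )
        return np.clip(out, 0.0, 1.0)

    return f


def _double_logistic_curve(peak_value, peak_doy, baseline, width):
    """Classic green-up/senescence double logistic (out-of-basis family)."""
    r_up, r_down = 8.0, 10.0
    t_up, t_down = peak_doy - width, peak_doy + width

    def f(d):
        d = np.asarray(d, float)
        shape = 1.0 / (1.0 + np.exp(-(d - t_up) / r_up)) + 1.0 / (
            1.0 + np.exp((d - t_down) / r_down)
        ) - 1.0
        return np.clip(baseline + (peak_value - baseline) * shape, 0.0, 1.0)

    return f


def _truncnorm(rng, mean, sd, lo, hi):
    """One normal draw truncated (by resampling) to [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    lo = max(lo, mean - 4 * sd)
    hi = min(hi, mean + 4 * sd)
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_phenology_curve(model: ClassPhenologyModel, rng_seed):
    """Draw one field's truth curve from a class phenology model.

    Returns a vectorised callable DOY -> NDVI in [0, 1].  Deterministic
    for a given seed; the curve's maximum value and timing fall within
    the model mean +/- 4 sd.  ``rng_seed`` may be an int or a Generator.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    v = _truncnorm(rng, model.peak_value_mean, model.peak_value_sd, 0.05, 1.0)
    d = _truncnorm(rng, model.peak_doy_mean, model.peak_doy_sd, SEASON_START, SEASON_END)
    if model.curve_family == "fourier":
        return _fourier_curve(v, d, model.baseline, model.sharpness)
    if model.curve_family == "double_logistic":
        return _double_logistic_curve(v, d, model.baseline, model.peak_width_days)
    sp = model.secondary_peak
    if sp is None:
        raise ConfigurationError("bimodal_mixture requires a secondary_peak")
    v2 = _truncnorm(rng, sp.value_mean, sp.value_sd, 0.05, 1.0)
    d2 = _truncnorm(rng, sp.doy_mean, sp.doy_sd, d + 14, SEASON_END + 14)
    return _bimodal_curve(v, d, v2, d2, model.baseline, model.peak_width_days)


@dataclass
class Field:
    field_id: int
    class_label: str
    polygon: object  # shapely polygon
    curve: object = None  # callable DOY -> NDVI

    @property
    def area_deg2(self) -> float:
        return self.polygon.area


@dataclass
class SceneStack:
    """Dated grids for one sensor over one season."""

    sensor_id: str
    grid: GridSpec
    year: int
    doys: np.ndarray
    nir: np.ndarray | None = None  # (n, H, W)
    red: np.ndarray | None = None
    ndvi: np.ndarray | None = None  # ready composites (60 m sensor)
    quality: np.ndarray | None = None  # SCL codes / QA integers
    drawn_bins: list | None = None  # cloud bin drawn per scene
    field_index: np.ndarray | None = None  # truth bookkeeping, (H, W)

    @property
    def n_scenes(self) -> int:
        return len(self.doys)


@dataclass
class SimulatedLandscape:
    """Fields, grids and ground truth of one synthetic scene collection."""

    config: LandscapeConfig
    rng_seed: int
    fields: list
    grid: GridSpec  # common 60 m target grid
    label_grid: np.ndarray  # class index per target cell, -1 background
    field_id_grid: np.ndarray  # field id per target cell, -1 background
    stacks: dict = field(default_factory=dict)  # sensor_id -> SceneStack

    @property
    def class_proportions(self) -> dict:
        areas = {c: 0.0 for c in CLASS_LABELS}
        for f in self.fields:
            areas[f.class_label] += f.area_deg2
        total = sum(areas.values())
        return {c: a / total for c, a in areas.items()}


def _layout_fields(config: LandscapeConfig, rng) -> list:
    """Tile the landscape with non-overlapping rectangular fields."""
    from shapely.geometry import box

    n = config.size_cells
    px = config.resolution_m / 111_000.0
    lo, hi = config.field_size_cells
    gap = config.field_gap_cells
    rects = []
    y = 0
    while y + lo <= n:
        h = int(rng.integers(lo, hi + 1))
        h = min(h, n - y)
        x = 0
        while x + lo <= n:
            w = int(rng.integers(lo, hi + 1))
            w = min(w, n - x)
            if h - gap >= 1 and w - gap >= 1:
                rects.append((x, y, w - gap, h - gap))
            x += w
        y += h
    fields = []
    for k, (x, y, w, h) in enumerate(rects):
        west = config.west + x * px
        north = config.north - y * px
        fields.append(
            Field(field_id=k, class_label="", polygon=box(west, north - h * px, west + w * px, north))
        )
    return fields


def _assign_classes(fields, proportions, rng):
    """Greedy area-quota assignment so class shares track the targets."""
    order = rng.permutation(len(fields))
    total = sum(f.area_deg2 for f in fields)
    assigned = {c: 0.0 for c in proportions}
    for i in order:
        deficits = {c: proportions[c] * total - assigned[c] for c in proportions}
        label = max(deficits, key=deficits.get)
        fields[i].class_label = label
        assigned[label] += fields[i].area_deg2
    return fields


def simulate_landscape(config: LandscapeConfig | None = None, rng_seed: int = 0) -> SimulatedLandscape:
    """Build fields, truth curves and the ground-truth grids (no scenes yet)."""
    config = config or LandscapeConfig()
    ss = np.random.SeedSequence([int(rng_seed), 0x5CE2E])
    rng_layout, rng_curves = (np.random.default_rng(s) for s in ss.spawn(2))

    fields = _layout_fields(config, rng_layout)
    if not fields:
        raise ConfigurationError("landscape too small to hold any field")
    _assign_classes(fields, config.proportions, rng_layout)
    for f in fields:
        f.curve = sample_phenology_curve(
            config.class_models[f.class_label], rng_curves.spawn(1)[0]
        )

    grid = build_target_grid(config.bounds, config.resolution_m)
    field_id_grid = rasterize_fields(
        [f.polygon for f in fields], grid, values=[f.field_id for f in fields]
    )
    label_grid = np.full(grid.shape, -1, np.int32)
    class_index = {c: i for i, c in enumerate(CLASS_LABELS)}
    for f in fields:
        label_grid[field_id_grid == f.field_id] = class_index[f.class_label]

    return SimulatedLandscape(
        config=config,
        rng_seed=int(rng_seed),
        fields=fields,
        grid=grid,
        label_grid=label_grid,
        field_id_grid=field_id_grid,
    )


def _schedule(sensor: SensorModel, rng) -> np.ndarray:
    if sensor.schedule == "daily":
        return np.arange(METEOR_START, METEOR_END + 1)
    if sensor.schedule == "jitter3":
        base = np.arange(SEASON_START, SEASON_END + 1, 3)
        days = base + rng.integers(-1, 2, size=base.size)
        return np.unique(np.clip(days, SEASON_START, SEASON_END))
    if sensor.schedule == "period11":
        days, d = [], SEASON_START + 2
        step = [11, 12]
        k = 0
        while d <= SEASON_END:
            days.append(d)
            d += step[k % 2]
            k += 1
        return np.asarray(days)
    raise ConfigurationError(f"unknown schedule {sensor.schedule!r}")


def _cloud_mask(shape, n_masked, rng):
    """Spatially coherent cloud of exactly ``n_masked`` pixels.

    Quasi-circular blobs grown from a few random seeds by a jittered
    distance transform, then thresholded at the exact pixel count.
    """
    H, W = shape
    total = H * W
    if n_masked <= 0:
        return np.zeros(shape, bool)
    if n_masked >= total:
        return np.ones(shape, bool)
    n_seeds = int(rng.integers(1, 5))
    seeds = np.zeros(shape, bool)
    seeds[rng.integers(0, H, n_seeds), rng.integers(0, W, n_seeds)] = True
    dist = ndimage.distance_transform_edt(~seeds)
    dist = dist + rng.uniform(0.0, 0.5, size=shape)  # roughen blob edges
    thresh = np.partition(dist.ravel(), n_masked - 1)[n_masked - 1]
    mask = dist <= thresh
    # jitter can tie; trim random extras for an exact count
    excess = int(mask.sum()) - n_masked
    if excess > 0:
        idx = np.flatnonzero(mask.ravel())
        drop = rng.choice(idx, size=excess, replace=False)
        mask.ravel()[drop] = False
    return mask


def generate_scene_stack(
    landscape: SimulatedLandscape, sensor: SensorModel, rng_seed: int
) -> SceneStack:
    """Render one sensor's full-season scene stack over the landscape.

    Per scene: pixel NDVI = field truth curve evaluated at
    (DOY - peak_shift), plus the sensor's additive bias, a fixed
    per-pixel spatial offset and Gaussian scene noise, clipped to
    [-1, 1].  Cloudy pixels (spatially coherent blobs whose masked
    fraction is drawn from the sensor's bin distribution) are
    overwritten with cloud-like values and encoded in the quality grid.
    """
    config = landscape.config
    sensor_key = zlib.crc32(sensor.sensor_id.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([landscape.rng_seed, sensor_key, int(rng_seed)])
    rng = np.random.default_rng(ss)

    doys = _schedule(sensor, rng)
    if doys.size == 0:
        raise ConfigurationError("empty acquisition schedule")
    grid = build_target_grid(config.bounds, sensor.native_resolution_m)
    field_index = rasterize_fields([f.polygon for f in landscape.fields], grid)

    # (n_fields + 1, n_scenes) truth values; last row is background
    eval_days = doys.astype(float) - sensor.peak_shift_days
    curve_vals = np.empty((len(landscape.fields) + 1, doys.size), np.float32)
    for k, f in enumerate(landscape.fields):
        curve_vals[k] = f.curve(eval_days)
    curve_vals[-1] = BACKGROUND_NDVI
    curve_vals += sensor.additive_bias

    lut = np.where(field_index < 0, len(landscape.fields), field_index)
    clean = curve_vals[lut.ravel()].T.reshape((doys.size,) + grid.shape)

    if config.spatial_sd > 0:
        clean = clean + rng.normal(0.0, config.spatial_sd, grid.shape).astype(np.float32)
    if sensor.noise_sd > 0:
        clean = clean + rng.normal(0.0, sensor.noise_sd, clean.shape).astype(np.float32)
    ndvi = np.clip(clean, -1.0, 1.0).astype(np.float32)

    quality = None
    drawn_bins = None
    if sensor.has_quality_layer:
        quality = np.empty(ndvi.shape, np.int32)
        drawn_bins = []
        dist = sensor.mask_fraction_distribution
        total = grid.width * grid.height
        for s in range(doys.size):
            if dist is None:
                bin_label = "<5"
                frac = 0.0
            else:
                bin_label = CLOUD_BINS[rng.choice(4, p=dist)]
                lo, hi = _BIN_FRACTION_RANGES[bin_label]
                frac = rng.uniform(lo, hi)
            drawn_bins.append(bin_label)
            cloud = _cloud_mask(grid.shape, int(round(frac * total)), rng)
            if cloud.any():
                ndvi[s][cloud] = np.clip(
                    rng.normal(0.05, 0.05, int(cloud.sum())), -1.0, 1.0
                ).astype(np.float32)
            if sensor.sensor_id == "landsat":
                q = np.where(cloud, 22280, LANDSAT_CLEAR_VALUE)
            else:  # SCL-style codes
                q = np.where(
                    cloud,
                    rng.choice([3, 8, 9, 10], size=grid.shape),
                    rng.choice([4, 5], size=grid.shape, p=[0.7, 0.3]),
                )
            quality[s] = q

    stack = SceneStack(
        sensor_id=sensor.sensor_id,
        grid=grid,
        year=config.year,
        doys=doys,
        quality=quality,
        drawn_bins=drawn_bins,
        field_index=field_index,
    )
    if sensor.emits_reflectance:
        # invertible encoding: NDVI of the pair reproduces ndvi exactly
        stack.red = (0.2 * (1.0 - ndvi)).astype(np.float32)
        stack.nir = (0.2 * (1.0 + ndvi)).astype(np.float32)
    else:
        stack.ndvi = ndvi
    return stack


def simulate(config: LandscapeConfig | None = None, rng_seed: int = 0) -> SimulatedLandscape:
    """Full simulation: landscape plus one scene stack per configured sensor."""
    landscape = simulate_landscape(config, rng_seed)
    for k, sensor in landscape.config.sensors.items():
        landscape.stacks[k] = generate_scene_stack(landscape, sensor, rng_seed)
    return landscape
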