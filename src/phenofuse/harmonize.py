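"""Multi-sensor harmonization onto the common 60 m weekly cube.

Each sensor's stack is processed at its native resolution first:
quality layers are decoded into validity masks, NDVI is computed from
the reflectance pair, masked observations become missing, and each
pixel's gapped series is reconstructed by the harmonic fit and
composited to the 26 weekly anchors (the 60 m daily-composite sensor
skips the fit and is composited directly).  The weekly layers are then
resampled with bilinear interpolation onto the common target grid and
assembled into one cube holding, per cell and week, one NDVI value per
sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, resample_bilinear
from .masking import CloudTally, landsat_validity, meteor_validity, sentinel_validity
from .synthetic import SceneStack
from .timeseries import (
    DEFAULT_MIN_OBS,
    N_WEEKS,
    WEEKLY_ANCHORS,
    compute_ndvi,
    fit_fourier_stack,
    meteor_weekly,
    reconstruct_daily_stack,
    weekly_composites,
)


class CubeError(ValueError):
    pass


@dataclass
class WeeklyCube:
    """Per-cell, per-week, per-sensor NDVI on the common grid.

    ``layers`` maps sensor id to a (26, H, W) float array with NaN for
    missing sensor-week combinations; ``label_grid`` / ``field_id_grid``
    carry the ground truth (-1 = background).
    """

    grid: GridSpec
    anchors: np.ndarray
    layers: dict
    label_grid: np.ndarray
    field_id_grid: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def sensors(self) -> tuple:
        return tuple(self.layers)

    def flag_grid(self) -> np.ndarray:
        """Boolean (H, W): True where every sensor-week value is present."""
        ok = np.ones(self.grid.shape, bool)
        for arr in self.layers.values():
            ok &= np.all(np.isfinite(arr), axis=0)
        return ok


def stack_weekly(stack: SceneStack, min_obs: int = DEFAULT_MIN_OBS):
    """Weekly NDVI layers (26, H, W) for one stack at native resolution.

    Returns ``(weekly, diagnostics)``; diagnostics carry the cloud-bin
    tally and pixel bookkeeping (fitted vs excluded).
    """
    H, W = stack.grid.shape
    tally = CloudTally()
    diag = {"sensor": stack.sensor_id, "n_scenes": stack.n_scenes}

    if stack.ndvi is not None and stack.quality is None:
        # ready daily composites: no QA layer, no harmonic fit
        series = stack.ndvi.reshape(stack.n_scenes, -1).astype(float)
        for s in range(stack.n_scenes):
            tally.add(meteor_validity(stack.ndvi[s]))
        weekly = meteor_weekly(stack.doys, series).reshape(N_WEEKS, H, W)
        diag["pixels_fitted"] = int(np.isfinite(weekly).all(axis=0).sum())
        diag["pixels_excluded"] = H * W - diag["pixels_fitted"]
        diag["cloud_tally"] = tally.as_dict()
        return weekly, diag

    if stack.nir is not None:
        ndvi = compute_ndvi(stack.nir, stack.red)
    else:
        ndvi = np.asarray(stack.ndvi, float)
    decode = sentinel_validity if stack.sensor_id != "landsat" else landsat_validity
    masked = np.empty_like(ndvi)
    for s in range(stack.n_scenes):
        vm = decode(stack.quality[s], doy=int(stack.doys[s]), year=stack.year)
        tally.add(vm)
        masked[s] = vm.apply(ndvi[s])

    series = masked.reshape(stack.n_scenes, -1)
    w, coef, rmse, n_obs = fit_fourier_stack(stack.doys, series, min_obs=min_obs)
    daily = reconstruct_daily_stack(w, coef)
    weekly = weekly_composites(daily).reshape(N_WEEKS, H, W)

    fitted = np.isfinite(w)
    diag["pixels_fitted"] = int(fitted.sum())
    diag["pixels_excluded"] = int((~fitted).sum())
    diag["median_rmse"] = float(np.nanmedian(rmse)) if fitted.any() else float("nan")
    diag["cloud_tally"] = tally.as_dict()
    return weekly, diag


def resample_weekly(weekly: np.ndarray, source_grid: GridSpec, target: GridSpec):
    """Bilinear resample of each weekly layer onto the target grid."""
    out = np.empty((weekly.shape[0],) + target.shape)
    for k in range(weekly.shape[0]):
        out[k] = resample_bilinear(weekly[k], source_grid, target)
    return out


def assemble_cube(
    weekly_by_sensor: dict,
    target: GridSpec,
    label_grid: np.ndarray,
    field_id_grid: np.ndarray,
    anchors=None,
    diagnostics=None,
) -> WeeklyCube:
    """Assemble resampled per-sensor weekly layers into one cube.

    Every layer must already be on ``target`` and share the weekly
    anchor grid; mismatches raise :class:`CubeError`.
    """
    anchors = WEEKLY_ANCHORS if anchors is None else np.asarray(anchors)
    layers = {}
    for sensor, arr in weekly_by_sensor.items():
        arr = np.asarray(arr, float)
        if arr.shape != (anchors.size,) + target.shape:
            raise CubeError(
                f"{sensor}: layer shape {arr.shape} does not match "
                f"{(anchors.size,) + target.shape} (anchor or grid mismatch)"
            )
        layers[sensor] = arr
    if np.asarray(label_grid).shape != target.shape:
        raise CubeError("label grid does not match the target grid")
    return WeeklyCube(
        grid=target,
        anchors=anchors,
        layers=layers,
        label_grid=np.asarray(label_grid),
        field_id_grid=np.asarray(field_id_grid),
        diagnostics=diagnostics or {},
    )


def harmonize_landscape(landscape, min_obs: int = DEFAULT_MIN_OBS) -> WeeklyCube:
    """Run mask -> fit -> weekly -> resample -> cube for a simulated landscape."""
    target = landscape.grid
    weekly_by_sensor = {}
    diagnostics = {}
    for sensor_id, stack in landscape.stacks.items():
        weekly, diag = stack_weekly(stack, min_obs=min_obs)
        if stack.grid == target:
            weekly_by_sensor[sensor_id] = weekly
        else:
            weekly_by_sensor[sensor_id] = resample_weekly(weekly, stack.grid, target)
        diagnostics[sensor_id] = diag
    return assemble_cube(
        weekly_by_sensor,
        target,
        landscape.label_grid,
        landscape.field_id_grid,
        diagnostics=diagnostics,
    )
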