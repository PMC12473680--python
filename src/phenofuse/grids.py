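"""Geographic grids, field rasterization and bilinear resampling.

All grids are axis-aligned, north-up rasters in geographic (lon/lat)
coordinates with a constant pixel size in degrees.  The pipeline's common
target grid uses the equatorial conversion 1 degree ~ 111 km, so a 60 m
cell is ~0.00054 degrees; latitude convergence is deliberately ignored
(a documented approximation of the harmonization scheme).

Conventions: row-major arrays, row 0 at the northern edge, 0-based
indices, half-open pixel extents, values located at cell centers.
Coordinates are always (longitude, latitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.strtree import STRtree

DEG_PER_METER = 1.0 / 111_000.0  # 1 deg ~ 111 km at the equator


class GridError(ValueError):
    """Configuration error in grid construction."""


class OverlapError(ValueError):
    """Raised when field polygons overlap on the target grid."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"overlapping field polygons: {self.pairs}")


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic raster grid.

    Parameters
    ----------
    west, north : float
        Coordinates of the outer corner of pixel (0, 0) in degrees.
    pixel_size : float
        Cell size in degrees (same in both axes), > 0.
    width, height : int
        Number of columns / rows.
    """

    west: float
    north: float
    pixel_size: float
    width: int
    height: int

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise GridError("pixel_size must be positive")
        if self.width < 1 or self.height < 1:
            raise GridError("grid must contain at least one cell")

    @property
    def east(self) -> float:
        return self.west + self.pixel_size * self.width

    @property
    def south(self) -> float:
        return self.north - self.pixel_size * self.height

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north)."""
        return (self.west, self.south, self.east, self.north)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every cell center, each (height, width)."""
        lon = self.west + (np.arange(self.width) + 0.5) * self.pixel_size
        lat = self.north - (np.arange(self.height) + 0.5) * self.pixel_size
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(
            lat[:, None], self.shape
        ).copy()

    def world_to_pixel(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (col, row) image coordinates of lon/lat points.

        The returned coordinates place cell centers at integer values,
        i.e. (0.0, 0.0) is the center of pixel (row 0, col 0).
        """
        col = (np.asarray(lon, float) - self.west) / self.pixel_size - 0.5
        row = (self.north - np.asarray(lat, float)) / self.pixel_size - 0.5
        return col, row

    def to_dict(self) -> dict:
        return {
            "west": self.west,
            "north": self.north,
            "pixel_size": self.pixel_size,
            "width": self.width,
            "height": self.height,
            "crs": "EPSG:4326",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(d["west"], d["north"], d["pixel_size"], d["width"], d["height"])


def build_target_grid(bounds, resolution_m: float) -> GridSpec:
    """Build the common classification grid from lon/lat bounds.

    ``bounds`` is (west, south, east, north) in degrees; ``resolution_m``
    the nominal metric cell size.  Pixel size is resolution_m / 111000
    degrees; the grid is snapped to the north-west corner of the bounds
    and extended to cover them fully.
    """
    west, south, east, north = map(float, bounds)
    if not (east > west and north > south):
        raise GridError(f"degenerate bounds {bounds}")
    if resolution_m <= 0:
        raise GridError("resolution must be positive")
    px = resolution_m * DEG_PER_METER
    width = int(np.ceil((east - west) / px - 1e-9))
    height = int(np.ceil((north - south) / px - 1e-9))
    return GridSpec(west=west, north=north, pixel_size=px, width=width, height=height)


BACKGROUND = -1  # label value for cells outside every field


def rasterize_fields(polygons, grid: GridSpec, values=None) -> np.ndarray:
    """Burn non-overlapping polygons into an integer grid by cell center.

    Parameters
    ----------
    polygons : sequence of shapely geometries
    values : sequence of int, optional
        Value burnt for each polygon; defaults to the polygon index.

    Returns
    -------
    ndarray of int, shape ``grid.shape``; cells whose center falls in no
    polygon hold :data:`BACKGROUND`.

    Raises
    ------
    OverlapError
        If two polygons overlap with positive area (ids of the pair
        reported).
    """
    polygons = list(polygons)
    if values is None:
        values = np.arange(len(polygons))
    values = np.asarray(values)

    if len(polygons) > 1:
        tree = STRtree(polygons)
        bad = set()
        for i, j in tree.query(polygons, predicate="intersects").T:
            if i < j and polygons[i].intersection(polygons[j]).area > 0:
                bad.add((int(i), int(j)))
        if bad:
            raise OverlapError(sorted(bad))

    out = np.full(grid.shape, BACKGROUND, dtype=np.int32)
    if not polygons:
        return out
    lon, lat = grid.cell_centers()
    pts = shapely.points(lon.ravel(), lat.ravel())
    tree = STRtree(pts)
    for k, poly in enumerate(polygons):
        idx = tree.query(poly, predicate="contains")
        out.ravel()[idx] = values[k]
    return out


def resample_bilinear(
    source: np.ndarray, source_grid: GridSpec, target: GridSpec
) -> np.ndarray:
    """Resample ``source`` onto ``target`` by bilinear interpolation.

    Each target cell takes the distance-weighted average of the four
    source cells nearest to its center.  A target cell becomes NaN when
    its center maps outside the source cell-center lattice or when any
    of its four neighbours is NaN (missing data are never blended).

    Raises
    ------
    GridError
        If the two grids do not overlap at all.
    """
    source = np.asarray(source, float)
    if source.shape != source_grid.shape:
        raise GridError("source array does not match its grid")
    if (
        target.west >= source_grid.east
        or target.east <= source_grid.west
        or target.north <= source_grid.south
        or target.south >= source_grid.north
    ):
        raise GridError("source and target grids do not overlap")

    lon, lat = target.cell_centers()
    col, row = source_grid.world_to_pixel(lon, lat)

    c0 = np.floor(col).astype(int)
    r0 = np.floor(row).astype(int)
    inside = (c0 >= 0) & (r0 >= 0) & (c0 + 1 < source_grid.width) & (
        r0 + 1 < source_grid.height
    )
    c0c = np.clip(c0, 0, source_grid.width - 2)
    r0c = np.clip(r0, 0, source_grid.height - 2)
    fx = col - c0
    fy = row - r0

    v00 = source[r0c, c0c]
    v01 = source[r0c, c0c + 1]
    v10 = source[r0c + 1, c0c]
    v11 = source[r0c + 1, c0c + 1]
    out = (
        v00 * (1 - fx) * (1 - fy)
        + v01 * fx * (1 - fy)
        + v10 * (1 - fx) * fy
        + v11 * fx * fy
    )
    out[~inside] = np.nan
    return out
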