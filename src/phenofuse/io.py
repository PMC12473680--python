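"""Readers and writers for scenes, fields and run manifests.

Scenes are stored as plain multi-band TIFF files (via tifffile) named
``<sensor>_<YYYYDDD>.tif`` together with a JSON sidecar
(``<name>.json``) carrying the georeferencing (grid spec, EPSG:4326),
the band names and the acquisition date; a scene without its sidecar
is rejected rather than silently assuming a location.  Field polygons
travel as GeoJSON with a ``class`` property restricted to the five
target labels.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

from .calibration import CLASS_LABELS
from .grids import GridSpec
from .synthetic import Field, SceneStack

SCENE_NAME_RE = re.compile(r"^(?P<sensor>[a-z]+)_(?P<year>\d{4})(?P<doy>\d{3})\.tif$")


class FormatError(ValueError):
    pass


class FieldDataError(ValueError):
    pass


def scene_filename(sensor_id: str, year: int, doy: int) -> str:
    return f"{sensor_id}_{year}{doy:03d}.tif"


def parse_scene_name(name: str):
    """``<sensor>_<YYYYDDD>.tif`` -> (sensor, year, doy)."""
    m = SCENE_NAME_RE.match(Path(name).name)
    if not m:
        raise FormatError(f"cannot parse scene date from filename {name!r}")
    return m["sensor"], int(m["year"]), int(m["doy"])


def write_scene(path, bands: dict, grid: GridSpec, year: int, doy: int, sensor_id: str):
    """Write one scene: band dict (name -> 2-d array) + JSON sidecar."""
    path = Path(path)
    names = list(bands)
    data = np.stack([np.asarray(bands[n]) for n in names])
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "grid": grid.to_dict(),
        "bands": names,
        "sensor": sensor_id,
        "year": year,
        "doy": doy,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_scene(path):
    """Read one scene written by :func:`write_scene`.

    Returns ``(bands, grid, meta)``; missing georeferencing (no sidecar
    or no grid entry) is an explicit :class:`FormatError`, and the date
    is cross-checked against the ``<sensor>_<YYYYDDD>`` filename.
    """
    path = Path(path)
    sensor, year, doy = parse_scene_name(path.name)
    side = path.with_suffix(".json")
    if not side.exists():
        raise FormatError(f"scene {path.name} has no georeferencing sidecar")
    meta = json.loads(side.read_text())
    if "grid" not in meta:
        raise FormatError(f"scene {path.name}: sidecar lacks a grid definition")
    grid = GridSpec.from_dict(meta["grid"])
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    names = meta.get("bands", [f"band{i}" for i in range(data.shape[0])])
    bands = {n: data[i] for i, n in enumerate(names)}
    meta.setdefault("sensor", sensor)
    meta.setdefault("year", year)
    meta.setdefault("doy", doy)
    return bands, grid, meta


def write_scene_stack(stack: SceneStack, out_dir) -> list:
    """Write every scene of a stack; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(stack.n_scenes):
        bands = {}
        if stack.nir is not None:
            bands["nir"] = stack.nir[s]
            bands["red"] = stack.red[s]
        if stack.ndvi is not None:
            bands["ndvi"] = stack.ndvi[s]
        if stack.quality is not None:
            bands["quality"] = stack.quality[s]
        p = out_dir / scene_filename(stack.sensor_id, stack.year, int(stack.doys[s]))
        write_scene(p, bands, stack.grid, stack.year, int(stack.doys[s]), stack.sensor_id)
        paths.append(p)
    return paths


def read_scene_stack(scene_dir, sensor_id: str) -> SceneStack:
    """Assemble a stack from ``<sensor>_<YYYYDDD>.tif`` files in a directory."""
    scene_dir = Path(scene_dir)
    paths = sorted(scene_dir.glob(f"{sensor_id}_*.tif"))
    if not paths:
        raise FormatError(f"no {sensor_id} scenes under {scene_dir}")
    doys, years, nir, red, ndvi, quality = [], [], [], [], [], []
    grid = None
    for p in paths:
        bands, g, meta = read_scene(p)
        grid = grid or g
        doys.append(meta["doy"])
        years.append(meta["year"])
        if "nir" in bands:
            nir.append(bands["nir"])
            red.append(bands["red"])
        if "ndvi" in bands:
            ndvi.append(bands["ndvi"])
        if "quality" in bands:
            quality.append(bands["quality"])
    order = np.argsort(doys)
    pick = lambda lst: np.stack([lst[i] for i in order]) if lst else None
    return SceneStack(
        sensor_id=sensor_id,
        grid=grid,
        year=int(years[0]),
        doys=np.asarray(doys)[order],
        nir=pick(nir),
        red=pick(red),
        ndvi=pick(ndvi),
        quality=pick(quality),
    )


def write_fields(fields, path):
    """Write field polygons as GeoJSON with a ``class`` property."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(f.polygon),
            "properties": {"field_id": f.field_id, "class": f.class_label},
        }
        for f in fields
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_fields(path):
    """Read and validate field polygons from GeoJSON.

    Unknown class labels raise :class:`FieldDataError` naming the
    feature; invalid geometries are repaired with ``make_valid`` where
    possible, otherwise rejected.  Returns ``(fields, report)``.
    """
    doc = json.loads(Path(path).read_text())
    fields, report = [], {"repaired": [], "rejected": []}
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {})
        label = props.get("class")
        if label not in CLASS_LABELS:
            raise FieldDataError(
                f"feature {props.get('field_id', k)}: unknown class label {label!r}"
            )
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            fixed = make_valid(geom)
            if fixed.is_valid and fixed.area > 0:
                geom = fixed
                report["repaired"].append(props.get("field_id", k))
            else:
                report["rejected"].append(props.get("field_id", k))
                continue
        fields.append(Field(field_id=int(props.get("field_id", k)), class_label=label, polygon=geom))
    return fields, report


@dataclass
class RunManifest:
    """Provenance record written once per pipeline output directory."""

    config_hash: str
    seed: int
    stages: dict = dc_field(default_factory=dict)  # stage -> record counts
    timestamp: str = ""

    def record(self, stage: str, **counts):
        bad = {k: v for k, v in counts.items() if isinstance(v, (int, float)) and v < 0}
        if bad:
            raise ValueError(f"negative manifest counts: {bad}")
        self.stages[stage] = counts

    def write(self, out_dir):
        self.timestamp = datetime.now(timezone.utc).isoformat()
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))
        return path


def config_hash(config) -> str:
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
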