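"""End-to-end orchestration: simulate -> mask -> fit -> harmonize ->
features -> classify -> evaluate -> map.

:func:`run_synthetic_experiment` is the in-memory reference experiment
used throughout the test-suite and the reproduction script: it builds
one synthetic landscape, harmonizes all sensors onto the common 60 m
weekly cube and reports grouped-split and cross-validation accuracy
for each single-sensor feature set and for the combined one.

:func:`run_pipeline` is the disk-backed variant behind the command
line: it additionally writes scenes, fields, cube layers, per-field
phenology summaries, metric JSON and a run manifest, and skips stages
whose outputs already exist for the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import LandscapeConfig
from .classify import (
    build_sample_table,
    dominant_class_map,
    feature_columns,
    group_split,
    iqr_filter,
    run_classification,
    stratified_group_cv,
    train_classifier,
)
from .harmonize import harmonize_landscape
from .io import RunManifest, config_hash, write_fields, write_scene_stack
from .phenology import summarize_field
from .synthetic import simulate

SENSOR_SETS = {
    "sentinel": ("sentinel",),
    "landsat": ("landsat",),
    "meteor": ("meteor",),
    "multisensor": ("sentinel", "landsat", "meteor"),
}


@dataclass
class ExperimentResult:
    seed: int
    n_fields: int
    n_cells: int
    split_reports: dict = field(default_factory=dict)  # set name -> EvaluationReport
    cv_reports: dict = field(default_factory=dict)
    field_map: pd.Series | None = None

    def oa(self, name: str, cv: bool = False) -> float:
        rep = (self.cv_reports if cv else self.split_reports)[name]
        return rep.oa

    def summary(self) -> str:
        lines = [f"Synthetic landscape (seed {self.seed}): "
                 f"{self.n_fields} fields, {self.n_cells} labeled cells"]
        lines.append(f"{'input':<14}{'split OA %':>11}{'CV OA %':>9}{'CV F1mean':>11}")
        for name in self.split_reports:
            cv = self.cv_reports.get(name)
            lines.append(
                f"{name:<14}{self.split_reports[name].oa:>11.1f}"
                + (f"{cv.oa:>9.1f}{cv.f1_mean:>11.2f}" if cv else "")
            )
        return "\n".join(lines)


def score_table(
    table: pd.DataFrame,
    sensor_sets: dict,
    rng_seed: int,
    with_cv: bool = True,
) -> tuple[dict, dict]:
    """Grouped-split and CV reports for every feature set on one table."""
    split_reports, cv_reports = {}, {}
    for name, sensors in sensor_sets.items():
        split_reports[name] = run_classification(table, sensors, rng_seed=rng_seed)
        if with_cv:
            cv_reports[name] = stratified_group_cv(
                table, feature_columns(table, sensors), rng_seed=rng_seed
            )
    return split_reports, cv_reports


def run_synthetic_experiment(
    rng_seed: int,
    config: LandscapeConfig | None = None,
    sensor_sets: dict | None = None,
    with_cv: bool = True,
    with_map: bool = False,
    table: pd.DataFrame | None = None,
) -> ExperimentResult:
    """Simulate one landscape and score every classifier input on it."""
    config = config or LandscapeConfig()
    sensor_sets = SENSOR_SETS if sensor_sets is None else sensor_sets
    if table is None:
        landscape = simulate(config, rng_seed)
        cube = harmonize_landscape(landscape)
        table = build_sample_table(cube)
        n_fields = len(landscape.fields)
    else:
        n_fields = int(table["field_id"].nunique())

    result = ExperimentResult(seed=int(rng_seed), n_fields=n_fields, n_cells=len(table))
    result.split_reports, result.cv_reports = score_table(
        table, sensor_sets, rng_seed, with_cv
    )
    if with_map and "multisensor" in sensor_sets:
        feats = feature_columns(table, sensor_sets["multisensor"])
        train, test = group_split(table, rng_seed=rng_seed)
        train, _, _ = iqr_filter(train, feats)
        model = train_classifier(train, feats, rng_seed=rng_seed)
        pred = pd.DataFrame(
            {"field_id": table["field_id"], "predicted": model.predict(table[feats].to_numpy())}
        )
        proba = pd.DataFrame(model.predict_proba(table[feats].to_numpy()),
                             columns=model.classes_, index=table.index)
        result.field_map = dominant_class_map(pred, proba)
    return result


def run_pipeline(config: dict, out_dir, rng_seed: int = 0, write_scenes: bool = False):
    """Disk-backed pipeline run with caching and a run manifest.

    ``config`` is a plain dict (e.g. parsed YAML) whose keys override
    :class:`LandscapeConfig` defaults.  A rerun with identical config
    and seed returns the cached metrics without recomputation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash({**config, "seed": int(rng_seed)})
    metrics_path = out_dir / "metrics.json"
    if metrics_path.exists():
        cached = json.loads(metrics_path.read_text())
        if cached.get("config_hash") == chash:
            return cached

    lc_kwargs = {k: v for k, v in config.items() if k in LandscapeConfig.__dataclass_fields__}
    lconfig = LandscapeConfig(**lc_kwargs)
    manifest = RunManifest(config_hash=chash, seed=int(rng_seed))

    landscape = simulate(lconfig, rng_seed)
    manifest.record("simulate", fields=len(landscape.fields),
                    scenes=sum(s.n_scenes for s in landscape.stacks.values()))
    write_fields(landscape.fields, out_dir / "fields.geojson")
    if write_scenes:
        for sensor_id, stack in landscape.stacks.items():
            write_scene_stack(stack, out_dir / "scenes" / sensor_id)

    cube = harmonize_landscape(landscape)
    for sensor_id, diag in cube.diagnostics.items():
        manifest.record(
            f"fit_{sensor_id}",
            scenes_read=diag["n_scenes"],
            pixels_fitted=diag["pixels_fitted"],
            pixels_excluded=diag["pixels_excluded"],
        )

    table = build_sample_table(cube)
    manifest.record("features", rows=len(table))
    summaries = [
        summarize_field(cube, f, "sentinel") for f in landscape.fields
        if (cube.field_id_grid == f.field_id).any()
    ]
    pd.DataFrame(
        [{"field_id": s.field_id, "class": s.class_label,
          "NDVImax": s.ndvi_max, "DOYmax": s.doy_max} for s in summaries]
    ).to_csv(out_dir / "field_phenology.csv", index=False)

    metrics = {"config_hash": chash, "seed": int(rng_seed), "inputs": {}}
    with_cv = bool(config.get("with_cv", True))
    result = run_synthetic_experiment(
        rng_seed, lconfig, with_cv=with_cv, with_map=True, table=table
    )
    for name, rep in result.split_reports.items():
        metrics["inputs"][name] = {"split": rep.to_dict()}
        if with_cv:
            metrics["inputs"][name]["cv"] = result.cv_reports[name].to_dict()
    if result.field_map is not None:
        result.field_map.to_csv(out_dir / "field_class_map.csv")
    metrics_path.write_text(json.dumps(metrics, indent=1))
    manifest.record("classify", inputs=len(metrics["inputs"]))
    manifest.write(out_dir)
    return metrics
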