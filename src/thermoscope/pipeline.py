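"""End-to-end orchestration: harmonise → exposure → fit → metrics → map.

A single config drives every stage; outputs land in a directory with a JSON
provenance manifest recording seeds, input digests and every intermediate
path, so a rerun with identical config and seeds reproduces identical
intermediates under the deterministic REML backend.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import exposure_for_species
from .models import ModelId, ModelSpec, build_design, fit_mixed, fit_pgls
from .plasticity import species_metrics
from .prediction import (
    apply_uncertainty_mask,
    climatological_layers_for,
    combine_realms,
    fit_acclimation_anchor,
    predict_layers,
)
from .simulate import SimulationConfig, load_bundle, make_bundle
from .tolerance import (
    DurationSlope,
    estimate_duration_slope,
    harmonise_records,
    records_to_frame,
    select_median_latitude,
)

log = logging.getLogger("thermoscope")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    bundle_dir: str | None = None  # existing inputs; if None, simulate
    simulate_n_species: int = 60
    simulate_grid: int = 12
    seed: int = 0
    slope_source: str = "fit"  # "fit" or "fixed:<value>"
    n_bootstrap: int = 50
    percentile: float = 97.5
    warming_rate: float | None = 0.02  # °C / yr, for t1/t2 outputs
    mask_sd_percentile: float = 90.0
    backend: str = "reml"
    models: tuple[str, ...] = ("model1", "model2", "model3", "pgls")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in doc:
            doc["models"] = tuple(doc["models"])
        return cls(**doc)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the provenance manifest.

    Any stage failure aborts with :class:`StageError` naming the stage;
    outputs of completed stages are retained on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": [],
        "outputs": {},
    }

    def finish_stage(name: str, paths: dict[str, Path]) -> None:
        entry = {"stage": name, "outputs": {}}
        for key, p in paths.items():
            entry["outputs"][key] = {"path": str(p), "sha256": _digest(Path(p))}
        manifest["stages"].append(entry)
        manifest["outputs"].update(entry["outputs"])
        log.info("stage %s complete (%d outputs)", name, len(paths))

    # --- inputs ----------------------------------------------------------
    try:
        if config.bundle_dir is None:
            from .simulate import GridSpec

            sim = SimulationConfig(
                n_species=config.simulate_n_species,
                grid=GridSpec(n_lat=config.simulate_grid, n_lon=config.simulate_grid),
            )
            bundle = make_bundle(sim, seed=config.seed)
            bundle_dir = out / "bundle"
            bundle.write(bundle_dir)
        else:
            bundle_dir = Path(config.bundle_dir)
        inputs = load_bundle(bundle_dir)
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc
    finish_stage(
        "inputs",
        {name: bundle_dir / fn for name, fn in [
            ("records", "records.csv"), ("tree", "tree.nwk"),
            ("fresh_cube", "fresh_temps.nc"), ("marine_cube", "marine_temps.nc"),
            ("masks", "range_masks.nc"),
        ]},
    )

    records, tree = inputs["records"], inputs["tree"]

    # --- harmonise -------------------------------------------------------
    try:
        if config.slope_source.startswith("fixed:"):
            slope = DurationSlope(
                float(config.slope_source.split(":", 1)[1]), 0.0, 1, "log10"
            )
        else:
            slope = estimate_duration_slope(
                records, n_bootstrap=config.n_bootstrap, rng_seed=config.seed
            )
        harmonised = harmonise_records(records, slope)
        hframe = records_to_frame(harmonised)
        harmonised_csv = out / "harmonised.csv"
        hframe.to_csv(harmonised_csv, index=False)
        rejections_csv = out / "rejections.csv"
        inputs["rejections"].to_csv(rejections_csv, index=False)
        slope_json = out / "duration_slope.json"
        slope_json.write_text(json.dumps(dataclasses.asdict(slope), indent=1))
    except Exception as exc:  # noqa: BLE001
        raise StageError("harmonise", exc) from exc
    finish_stage("harmonise", {
        "harmonised": harmonised_csv, "rejections": rejections_csv,
        "duration_slope": slope_json,
    })

    # --- exposure --------------------------------------------------------
    try:
        realms = inputs["realms"]
        exposure, skipped = exposure_for_species(
            inputs["fresh_cube"], inputs["marine_cube"], inputs["masks"],
            realms, percentile=config.percentile,
        )
        exposure_csv = out / "exposure.csv"
        exposure.to_csv(exposure_csv, index=False)
        skipped_txt = out / "exposure_skipped.txt"
        skipped_txt.write_text("\n".join(skipped))
    except Exception as exc:  # noqa: BLE001
        raise StageError("exposure", exc) from exc
    finish_stage("exposure", {"exposure": exposure_csv, "skipped": skipped_txt})

    # --- fit -------------------------------------------------------------
    try:
        model_table = hframe.merge(
            exposure[["species", "max_habitat_temp", "thermal_variability"]],
            on="species", how="inner",
        )
        fits: dict[str, Path] = {}
        fit_objects = {}
        for mid in ("model1", "model2", "model3"):
            if mid not in config.models:
                continue
            table = model_table.dropna(
                subset=["heat_tolerance_std", "acclimation_std"]
                + (["latitude"] if mid == "model1" else [])
            )
            spec = ModelSpec(ModelId(mid), backend=config.backend)
            y, X, design = build_design(table, spec)
            fit = fit_mixed(
                y, X, tree, table["species"].to_numpy(str), spec, design,
                seed=config.seed,
            )
            path = out / f"fit_{mid}.json"
            fit.to_json(path)
            fits[mid] = path
            fit_objects[mid] = fit
        if "pgls" in config.models:
            species_table = _species_level_table(hframe, exposure)
            for response, tag in [
                ("max_habitat_temp", "pgls_maxT"),
                ("thermal_variability", "pgls_cv"),
            ]:
                spec = ModelSpec(ModelId.PGLS_EXPOSURE, response=response)
                y, X, design = build_design(species_table, spec)
                fit = fit_pgls(
                    y, X, tree, species_table["species"].tolist(), design
                )
                path = out / f"fit_{tag}.json"
                fit.to_json(path)
                fits[tag] = path
                fit_objects[tag] = fit
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit", exc) from exc
    finish_stage("fit", fits)

    # --- metrics ---------------------------------------------------------
    try:
        realm_fit = fit_objects.get("model3") or fit_objects.get("model2")
        if realm_fit is None:
            raise ValueError("metrics need a model-2 or model-3 fit")
        metrics = species_metrics(
            realm_fit, exposure, warming_rate=config.warming_rate
        )
        metrics_csv = out / "metrics.csv"
        metrics.to_csv(metrics_csv, index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("metrics", exc) from exc
    finish_stage("metrics", {"metrics": metrics_csv})

    # --- map -------------------------------------------------------------
    try:
        fit3 = fit_objects.get("model3")
        if fit3 is None:
            raise ValueError("global mapping needs a model-3 fit")
        anchor = fit_acclimation_anchor(hframe, exposure)
        layer_paths = {}
        per_realm = {}
        for tag, cube in [
            ("freshwater", inputs["fresh_cube"]), ("marine", inputs["marine_cube"]),
        ]:
            maxT, cv = climatological_layers_for(cube)
            layers = predict_layers(fit3, maxT, cv, tag, anchor)
            layers = apply_uncertainty_mask(
                layers, percentile=config.mask_sd_percentile
            )
            per_realm[tag] = layers
        combined = combine_realms(per_realm["freshwater"], per_realm["marine"])
        layers_nc = out / "layers.nc"
        combined.to_netcdf(layers_nc)
        sidecar = out / "layers_meta.json"
        sidecar.write_text(json.dumps({
            "anchor": dataclasses.asdict(anchor),
            "metadata": _jsonable(combined.metadata),
            "seed": config.seed,
        }, indent=1))
        layer_paths.update({"layers": layers_nc, "layers_meta": sidecar})
    except Exception as exc:  # noqa: BLE001
        raise StageError("map", exc) from exc
    finish_stage("map", layer_paths)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _species_level_table(hframe: pd.DataFrame, exposure: pd.DataFrame) -> pd.DataFrame:
    """One row per species: exposure joined with the median-latitude record."""
    from .tolerance import ToleranceRecord  # noqa: F401  (documentation aid)

    rows = []
    for sp, grp in hframe.groupby("species"):
        with_lat = grp.dropna(subset=["latitude"])
        if with_lat.empty:
            continue
        distinct = np.sort(with_lat["latitude"].unique())
        lat = distinct[(len(distinct) - 1) // 2]
        rows.append({"species": sp, "latitude": float(lat)})
    lat_table = pd.DataFrame(rows)
    merged = exposure.merge(lat_table, on="species", how="inner")
    merged["abs_latitude"] = merged["latitude"].abs()
    return merged
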