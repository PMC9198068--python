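"""Pipeline drivers: in-memory study runner and the file-based pipeline.

``run_study`` chains simulation (or pre-built tables) through indicators,
PCA scoring, density-weighted aggregation and validation — the workhorse
for tests and calibration experiments.  ``run_pipeline`` is the file-based
equivalent: it reads the input artifacts named in a :class:`PipelineConfig`,
runs the same stages, and writes every output plus a manifest recording the
configuration hash, so identical configurations are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as pio
from .aggregation import aggregate_scores, assign_regions
from .errors import SchemaError, StageError
from .geosurface import fit_surface, normalize_surface, predict_grid
from .indicators import indicator_matrix
from .pca import PdiModel, fit_pdi_model, score_households
from .raster import write_ascii_grid
from .synthetic import SyntheticConfig, SyntheticDataset, simulate
from .validation import build_report

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything produced by one in-memory end-to-end run."""

    dataset: SyntheticDataset
    model: PdiModel
    scores: pd.DataFrame
    aggregates: pd.DataFrame          # requested level, density per use_density
    aggregates_raw: pd.DataFrame      # same level, sample weights only
    matrix: np.ndarray
    report: Any


def run_study(config: SyntheticConfig, level: str = "admin1",
              use_density: bool = True) -> StudyResult:
    """Simulate a survey world and push it through the full index pipeline."""
    ds = simulate(config)
    X, ids, _ = indicator_matrix(ds.households)
    model = fit_pdi_model(X)
    scores = pd.DataFrame({"household_id": ids, "score": score_households(model, X)})
    agg = aggregate_scores(scores, ds.households, ds.clusters, ds.raster,
                           level=level, use_density=use_density)
    agg_raw = aggregate_scores(scores, ds.households, ds.clusters, ds.raster,
                               level=level, use_density=False)
    truth = ds.regional_truth if level == "admin1" else None
    report = build_report(agg, caseloads=ds.caseloads if level == "admin1" else None,
                          matrix=X, truth=truth)
    return StudyResult(dataset=ds, model=model, scores=scores, aggregates=agg,
                       aggregates_raw=agg_raw, matrix=X, report=report)


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """File paths and options for one pipeline run."""

    households: str
    clusters: str
    regions: str
    raster: str
    out_dir: str
    caseloads: str | None = None
    truth: str | None = None
    level: str = "admin1"
    use_density: bool = True
    normalization_domain: tuple[float, float] | None = None
    surface: bool = False
    surface_cell_size: float = 0.05
    surface_lambda: float | str = "auto"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.level not in ("admin0", "admin1"):
            raise SchemaError(f"level must be admin0 or admin1, got {self.level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: pipeline config must be a mapping")
        if raw.get("normalization_domain") is not None:
            raw["normalization_domain"] = tuple(raw["normalization_domain"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise SchemaError(f"{path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if d["normalization_domain"] is not None:
            d["normalization_domain"] = list(d["normalization_domain"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Read inputs, run all stages, write artifacts and a manifest.

    Outputs: model JSON, household scores CSV, aggregates CSV (sample-weight
    and density-weighted variants side by side), normalized index CSV,
    optional surface mean/sd grids, validation report CSV, and
    manifest.json with the config hash, seed and per-stage counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}

    households = _stage("read_households")(pio.read_households)(config.households)
    clusters = _stage("read_clusters")(pio.read_clusters)(config.clusters)
    regions = _stage("read_regions")(pio.read_regions)(config.regions)
    raster = _stage("read_raster")(pio.read_ascii_grid)(config.raster)
    caseloads = (
        _stage("read_caseloads")(pio.read_caseloads)(config.caseloads)
        if config.caseloads else None
    )
    counts["households_read"] = len(households)
    counts["clusters_read"] = len(clusters)
    counts["regions_read"] = len(regions)

    clusters = _stage("assign_regions")(assign_regions)(clusters, regions)

    @_stage("indicators")
    def _indicators():
        return indicator_matrix(households)

    X, ids, excl = _indicators()
    counts["households_excluded"] = int(sum(excl.values()))

    @_stage("index")
    def _index():
        model = fit_pdi_model(X)
        return model, pd.DataFrame(
            {"household_id": ids, "score": score_households(model, X)}
        )

    model, scores = _index()

    @_stage("aggregate")
    def _aggregate():
        agg = aggregate_scores(
            scores, households, clusters, raster, level=config.level,
            use_density=config.use_density,
            normalization_domain=config.normalization_domain,
        )
        return agg

    aggregates = _aggregate()
    counts["regions_aggregated"] = len(aggregates)

    paths: dict[str, Path] = {
        "model": out / "pdi_model.json",
        "scores": out / "scores.csv",
        "aggregates": out / "aggregates.csv",
        "index": out / "pdi_normalized.csv",
        "manifest": out / "manifest.json",
    }
    model.to_json(paths["model"])
    scores.to_csv(paths["scores"], index=False)
    aggregates.to_csv(paths["aggregates"], index=False)
    aggregates[["region_id", "level", "pdi_normalized"]].to_csv(
        paths["index"], index=False)

    if config.surface:
        @_stage("surface")
        def _surface():
            cl_scores = scores.merge(
                households[["household_id", "cluster_id"]], on="household_id"
            ).groupby("cluster_id")["score"].agg(["mean", "size"]).reset_index()
            pts = cl_scores.merge(clusters[["cluster_id", "lon", "lat"]],
                                  on="cluster_id")
            pts = pts.rename(columns={"mean": "mean_score", "size": "n_households"})
            lon_min, lat_min, lon_max, lat_max = raster.extent
            surf = fit_surface(pts, lam=config.surface_lambda,
                               domain=(lon_min, lat_min, lon_max, lat_max))
            cell = config.surface_cell_size
            n_cols = int((lon_max - lon_min) / cell)
            n_rows = int((lat_max - lat_min) / cell)
            return predict_grid(surf, lon_min, lat_max, cell, n_rows, n_cols)

        mean_grid, sd_grid = _surface()
        paths["surface_mean"] = out / "surface_mean.asc"
        paths["surface_sd"] = out / "surface_sd.asc"
        paths["surface_normalized"] = out / "surface_normalized.asc"
        write_ascii_grid(mean_grid, paths["surface_mean"])
        write_ascii_grid(sd_grid, paths["surface_sd"])
        write_ascii_grid(normalize_surface(mean_grid), paths["surface_normalized"])

    truth = None
    if config.truth:
        truth_field = pd.read_csv(config.truth)
        truth = (truth_field.groupby("region_id", as_index=False)["deprivation"]
                 .mean().rename(columns={"deprivation": "true_deprivation"}))

    @_stage("validate")
    def _validate():
        return build_report(aggregates, caseloads=caseloads, matrix=X, truth=truth)

    report = _validate()
    paths["validation"] = out / "validation.csv"
    report.to_frame().to_csv(paths["validation"], index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "outputs": sorted(p.name for p in paths.values()),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", counts)
    return paths
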