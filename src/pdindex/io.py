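"""Readers and writers for the pipeline's tabular and geographic formats.

CSV tables are UTF-8, comma-separated, with a required header row.  Regions
travel as RFC 7946 GeoJSON FeatureCollections of Polygons (lon-lat order)
with a ``region_id`` (and optionally ``country_id``) property.  Rasters use
the ESRI ASCII grid format (see :mod:`pdindex.raster`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import SchemaError
from .raster import read_ascii_grid, write_ascii_grid  # re-exported

__all__ = [
    "read_households", "read_clusters", "read_caseloads", "read_scores",
    "read_regions", "write_regions", "regions_from_boxes",
    "read_ascii_grid", "write_ascii_grid", "Region",
]

HOUSEHOLD_COLUMNS = {
    "household_id": str,
    "cluster_id": str,
    "sample_weight": float,
    "toilet_sharing_count": int,
    "water_public": int,
    "n_members": int,
    "n_sleeping_rooms": int,
    "has_mobile": int,
    "has_vehicle": int,
}
CLUSTER_COLUMNS = {"cluster_id": str, "lon": float, "lat": float,
                   "urban": int, "region_id": str}
CASELOAD_COLUMNS = {"region_id": str, "cumulative_cases": int}
SCORE_COLUMNS = {"household_id": str, "score": float}


def _read_csv(path: str | Path, schema: dict[str, type],
              optional: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in schema if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    bad_lines: dict[str, list[int]] = {}
    for col, typ in schema.items():
        if col not in df.columns:
            continue
        if typ is str:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & converted.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            bad_lines[col] = [int(i) + 2 for i in bad[:10]]
        df[col] = converted
    if bad_lines:
        raise SchemaError(
            f"{path}: malformed numeric values (column -> line numbers): {bad_lines}"
        )
    return df


def read_households(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, HOUSEHOLD_COLUMNS)
    if (pd.to_numeric(df["sample_weight"], errors="coerce") <= 0).any():
        raise SchemaError(f"{path}: sample_weight must be strictly positive")
    if (pd.to_numeric(df["n_members"], errors="coerce") < 1).any():
        raise SchemaError(f"{path}: n_members must be at least 1")
    return df


def read_clusters(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {**CLUSTER_COLUMNS, "country_id": str},
                     optional=("country_id",))


def read_caseloads(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, CASELOAD_COLUMNS)
    if (df["cumulative_cases"] < 0).any():
        raise SchemaError(f"{path}: cumulative_cases must be non-negative")
    return df


def read_scores(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# Regions (GeoJSON)
# ---------------------------------------------------------------------------

@dataclass
class Region:
    region_id: str
    country_id: str | None
    geometry: BaseGeometry


def regions_from_boxes(boxes: pd.DataFrame) -> list[Region]:
    """Build Region objects from a rectangle table (synthetic generator output)."""
    from shapely.geometry import box

    return [
        Region(
            region_id=str(r.region_id),
            country_id=str(r.country_id) if "country_id" in boxes.columns else None,
            geometry=box(r.lon_min, r.lat_min, r.lon_max, r.lat_max),
        )
        for r in boxes.itertuples(index=False)
    ]


def write_regions(regions: list[Region], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"region_id": r.region_id,
                               "country_id": r.country_id},
                "geometry": mapping(r.geometry),
            }
            for r in regions
        ],
    }
    Path(path).write_text(json.dumps(fc, indent=1) + "\n")


def read_regions(path: str | Path) -> list[Region]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    fc = json.loads(path.read_text())
    if fc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    out: list[Region] = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise SchemaError(f"{path}: feature {i} lacks the region_id property")
        out.append(Region(
            region_id=str(props["region_id"]),
            country_id=(str(props["country_id"])
                        if props.get("country_id") is not None else None),
            geometry=shape(feat["geometry"]),
        ))
    if not out:
        raise SchemaError(f"{path}: no region features found")
    return out


# ---------------------------------------------------------------------------
# Synthetic dataset writer
# ---------------------------------------------------------------------------

def write_dataset(dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every table of a synthetic dataset; returns the path map.

    The truth CSV (latent cluster values) exists for oracle tests and
    validation, not as a pipeline input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "households": out / "households.csv",
        "clusters": out / "clusters.csv",
        "regions": out / "regions.geojson",
        "raster": out / "density.asc",
        "caseloads": out / "caseloads.csv",
        "truth": out / "truth.csv",
    }
    dataset.households.to_csv(paths["households"], index=False)
    dataset.clusters.to_csv(paths["clusters"], index=False)
    write_regions(regions_from_boxes(dataset.regions), paths["regions"])
    write_ascii_grid(dataset.raster, paths["raster"])
    dataset.caseloads.to_csv(paths["caseloads"], index=False)
    dataset.field.to_csv(paths["truth"], index=False)
    return paths
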