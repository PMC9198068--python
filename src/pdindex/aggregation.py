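"""Survey-weighted regional aggregation and min-max normalization.

Household scores are averaged to admin-0 (country) or admin-1 (region)
level using the survey sample weight, optionally multiplied by
ln(1 + population density) looked up at the household's (public, displaced)
cluster coordinates.  The natural log is used; any other base rescales all
weights by one constant and leaves every weighted mean unchanged.
Aggregates are then min-max normalized to [0, 1] across units of the same
level, so 1 marks the most deprived (least able to distance) unit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateRangeError, SchemaError
from .raster import DensityRaster

logger = logging.getLogger(__name__)

LEVELS = {"admin0": "country_id", "admin1": "region_id"}


def lookup_density(raster: DensityRaster, lon: float, lat: float) -> float:
    """Density (people/km2) of the raster cell containing the point.

    Cells are half-open ``[west, east) x (south, north]``; a point outside
    the raster extent raises, naming the point.
    """
    return raster.lookup(lon, lat)


def normalize(values, domain: tuple[float, float] | None = None) -> np.ndarray:
    """Min-max normalize to [0, 1]; monotone, observed min -> 0 and max -> 1.

    ``domain`` supplies an explicit (min, max) reference range; otherwise
    the observed range is used.  A zero-width range is an error.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = domain if domain is not None else (float(v.min()), float(v.max()))
    if hi <= lo:
        raise DegenerateRangeError(f"degenerate normalization range [{lo}, {hi}]")
    return (v - lo) / (hi - lo)


def assign_regions(clusters: pd.DataFrame, regions) -> pd.DataFrame:
    """Attach region_id/country_id to clusters by point-in-polygon.

    ``regions`` is a sequence of objects with region_id, country_id and a
    shapely geometry (see :func:`pdindex.io.read_regions`).  Boundary
    points count as inside (shapely ``intersects``). Clusters falling in no
    region get a null id and are logged.
    """
    from shapely.geometry import Point

    region_ids, country_ids = [], []
    for lon, lat in zip(clusters["lon"], clusters["lat"]):
        pt = Point(lon, lat)
        hit = next((r for r in regions if r.geometry.intersects(pt)), None)
        region_ids.append(hit.region_id if hit else None)
        country_ids.append(hit.country_id if hit else None)
    out = clusters.copy()
    out["region_id"] = region_ids
    out["country_id"] = country_ids
    n_miss = sum(r is None for r in region_ids)
    if n_miss:
        logger.warning("%d clusters fall outside every region polygon", n_miss)
    return out


def aggregate_scores(
    scores: pd.DataFrame,
    households: pd.DataFrame,
    clusters: pd.DataFrame,
    raster: DensityRaster | None = None,
    level: str = "admin1",
    use_density: bool = True,
    normalization_domain: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Aggregate household scores to regional deprivation indices.

    ``scores`` has columns household_id, score; ``households`` links
    household_id -> cluster_id and carries sample_weight; ``clusters``
    carries cluster coordinates plus the admin ids.  Returns one row per
    admin unit with the sample-weight-only mean (pdi_raw), the
    density-weighted mean (pdi_density_weighted, equal to pdi_raw when no
    raster is given), the normalized index of the selected variant, the
    household count and the mean log-density weight.
    """
    if level not in LEVELS:
        raise SchemaError(f"level must be one of {sorted(LEVELS)}, got {level!r}")
    if use_density and raster is None:
        raise SchemaError("density weighting requested but no raster given")
    key = LEVELS[level]
    if key not in clusters.columns:
        raise SchemaError(f"clusters table lacks the {key!r} column needed for {level}")

    df = scores.merge(
        households[["household_id", "cluster_id", "sample_weight"]],
        on="household_id", how="inner", validate="one_to_one",
    ).merge(
        clusters[["cluster_id", "lon", "lat", key]].rename(columns={key: "unit"}),
        on="cluster_id", how="inner",
    )
    if len(df) < len(scores):
        logger.warning("%d scored households had no cluster/region match and "
                       "were dropped", len(scores) - len(df))
    df = df[df["unit"].notna()]
    if (df["sample_weight"] <= 0).any():
        raise SchemaError("sample weights must be strictly positive")

    if raster is not None:
        dens_by_cluster = {
            cid: raster.lookup(lon, lat)
            for cid, lon, lat in clusters[["cluster_id", "lon", "lat"]].itertuples(
                index=False)
        }
        df["log_density"] = np.log1p(df["cluster_id"].map(dens_by_cluster))
    else:
        df["log_density"] = np.nan

    def one_unit(g: pd.DataFrame) -> pd.Series:
        w = g["sample_weight"].to_numpy()
        s = g["score"].to_numpy()
        raw = float(np.average(s, weights=w))
        if raster is not None:
            wd = w * g["log_density"].to_numpy()
            dens = float(np.average(s, weights=wd)) if wd.sum() > 0 else raw
        else:
            dens = raw
        return pd.Series({
            "pdi_raw": raw,
            "pdi_density_weighted": dens,
            "n_households": len(g),
            "mean_log_density": float(g["log_density"].mean()),
        })

    agg = (df.groupby("unit", sort=True).apply(one_unit, include_groups=False)
           .reset_index().rename(columns={"unit": "region_id"}))
    agg["n_households"] = agg["n_households"].astype(int)
    agg.insert(1, "level", level)

    target = "pdi_density_weighted" if use_density else "pdi_raw"
    agg["pdi_normalized"] = normalize(agg[target].to_numpy(), normalization_domain)
    return agg
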