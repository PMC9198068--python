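"""Synthetic DHS-like survey world generator.

Emulates the statistical structure the downstream index pipeline assumes:
households sampled in geographic clusters; a single spatially correlated
latent deprivation factor driving all five infrastructure indicators;
positive survey sample weights; anonymizing random displacement of cluster
GPS coordinates; a population-density raster; and regional cumulative
epidemic caseloads positively associated with latent risk.

Default calibration targets continental averages reported for African DHS
samples: 45% of households share a toilet (with about two other households
on average), 40% rely only on a public water source, 3.2 persons per
sleeping room, roughly 30% without a mobile phone and 50% without any
vehicle.

All randomness flows from a single seed; sub-generators (latent field,
households, displacement, raster, caseloads) draw from deterministically
spawned child streams, so identical configs give identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri  # inverse standard normal CDF

from .errors import ConfigurationError
from .raster import DensityRaster

EARTH_RADIUS_KM = 6371.0088

#: Marginal calibration targets for the five indicators (deprivation coding).
DEFAULT_CALIBRATION: dict[str, float] = {
    "shared_toilet_rate": 0.45,   # P(toilet shared with >= 1 other household)
    "mean_extra_sharers": 2.0,    # mean number of other sharing households, among sharers
    "public_water_rate": 0.40,    # P(only access is a public/open source)
    "no_mobile_rate": 0.30,       # P(no mobile phone in household)
    "no_vehicle_rate": 0.50,      # P(no bicycle/motorbike/car)
    "persons_per_room_mean": 3.2, # E[members / sleeping rooms]
    "household_size_mean": 4.8,   # E[members]
}

# Correction for the rooms rounding/flooring in the persons-per-room link,
# estimated once by Monte Carlo at the default configuration: the realized
# mean of members/rooms divided by the mean of the lognormal target.
_PPR_ROUNDING_FACTOR = 0.890

# The extra-sharers count is drawn only for households that share a toilet,
# which selects high-liability households; this factor (Monte Carlo, default
# configuration) deflates the Poisson base rate so the mean count among
# sharers hits `mean_extra_sharers` + 1 households sharing one toilet.
_SHARERS_SELECTION_FACTOR = 0.653

#: Log-scale slope of the persons-per-room target on the household liability.
_PPR_SLOPE = 0.5
#: Log-scale slope of the extra-sharers count on the household liability.
_SHARERS_SLOPE = 0.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the synthetic survey world.

    Regions are axis-aligned rectangles tiling a grid; each grid row of
    regions forms one "country" (admin-0 unit) so both aggregation levels
    are exercised.  ``factor_sd`` is the marginal standard deviation of the
    latent cluster deprivation; ``nugget_share`` is the fraction of that
    variance that is spatially independent cluster noise, the rest follows
    an exponential-kernel Gaussian process with range
    ``factor_spatial_range`` (degrees). ``indicator_noise_sd`` is the
    household-level liability noise, on the same scale as ``factor_sd``.
    """

    seed: int = 0
    n_regions: int = 30
    clusters_per_region: int = 20
    households_per_cluster: int = 25
    region_size_deg: float = 1.0
    factor_spatial_range: float = 1.0
    factor_sd: float = 1.0
    nugget_share: float = 0.3
    indicator_noise_sd: float = 0.5
    indicator_calibration: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION)
    )
    density_range: tuple[float, float] = (1.0, 2000.0)
    caseload_effect: float = 1.0
    caseload_baseline: float = 300.0
    caseload_dispersion_sd: float = 1.0
    grid_cell_size: float = 0.1
    displacement_urban_km: float = 2.0
    displacement_rural_km: float = 5.0
    urban_fraction: float = 0.35
    weight_log_sd: float = 0.2

    def __post_init__(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "clusters_per_region": self.clusters_per_region,
            "households_per_cluster": self.households_per_cluster,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {v}")
        if self.grid_cell_size <= 0 or self.region_size_deg <= 0:
            raise ConfigurationError("cell and region sizes must be positive")
        for name in ("factor_sd", "indicator_noise_sd", "factor_spatial_range",
                     "caseload_dispersion_sd", "weight_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0 <= self.nugget_share <= 1:
            raise ConfigurationError("nugget_share must lie in [0, 1]")
        if not 0 <= self.urban_fraction <= 1:
            raise ConfigurationError("urban_fraction must lie in [0, 1]")
        lo, hi = self.density_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("density_range must satisfy 0 <= min <= max")
        if self.displacement_urban_km < 0 or self.displacement_rural_km < 0:
            raise ConfigurationError("displacement radii must be non-negative")
        cal = dict(DEFAULT_CALIBRATION)
        cal.update(self.indicator_calibration)
        object.__setattr__(self, "indicator_calibration", cal)

    # -- region grid geometry -------------------------------------------------

    @property
    def n_grid_cols(self) -> int:
        return int(math.ceil(math.sqrt(self.n_regions)))

    def region_boxes(self) -> pd.DataFrame:
        """One row per region: id, country id, and rectangle bounds (degrees)."""
        rows = []
        size = self.region_size_deg
        for r in range(self.n_regions):
            gi, gj = divmod(r, self.n_grid_cols)
            rows.append({
                "region_id": f"R{r + 1:03d}",
                "country_id": f"C{gi + 1:02d}",
                "lon_min": gj * size,
                "lat_min": gi * size,
                "lon_max": (gj + 1) * size,
                "lat_max": (gi + 1) * size,
            })
        return pd.DataFrame(rows)

    def bounding_box(self) -> tuple[float, float, float, float]:
        boxes = self.region_boxes()
        return (
            float(boxes.lon_min.min()), float(boxes.lat_min.min()),
            float(boxes.lon_max.max()), float(boxes.lat_max.max()),
        )


_STREAMS = ("latent", "households", "displacement", "raster", "caseloads")


def _child_rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


# ---------------------------------------------------------------------------
# Latent field
# ---------------------------------------------------------------------------

def generate_latent_field(config: SyntheticConfig) -> pd.DataFrame:
    """Place clusters in their regions and draw latent deprivation.

    Deprivation is a zero-mean Gaussian field with marginal sd
    ``factor_sd``: an exponential-kernel spatial process carrying
    ``1 - nugget_share`` of the variance plus independent cluster noise.
    Columns: cluster_id, region_id, country_id, true_lon, true_lat, urban,
    deprivation.
    """
    rng = _child_rng(config, "latent")
    boxes = config.region_boxes()
    per = config.clusters_per_region
    n = config.n_regions * per

    lon = np.empty(n)
    lat = np.empty(n)
    region = np.empty(n, dtype=object)
    country = np.empty(n, dtype=object)
    for i, box in boxes.iterrows():
        sl = slice(i * per, (i + 1) * per)
        lon[sl] = rng.uniform(box.lon_min, box.lon_max, per)
        lat[sl] = rng.uniform(box.lat_min, box.lat_max, per)
        region[sl] = box.region_id
        country[sl] = box.country_id

    urban = rng.random(n) < config.urban_fraction

    var = config.factor_sd ** 2
    spatial_var = (1.0 - config.nugget_share) * var
    nugget_var = config.nugget_share * var
    z_spatial = np.zeros(n)
    if spatial_var > 0:
        if config.factor_spatial_range > 0:
            dx = lon[:, None] - lon[None, :]
            dy = lat[:, None] - lat[None, :]
            dist = np.hypot(dx, dy)
            K = spatial_var * np.exp(-dist / config.factor_spatial_range)
            K[np.diag_indices_from(K)] += 1e-9 * max(var, 1.0)
            L = np.linalg.cholesky(K)
            z_spatial = L @ rng.standard_normal(n)
        else:
            # zero range: the process degenerates to independent noise
            z_spatial = math.sqrt(spatial_var) * rng.standard_normal(n)
    z_nugget = (
        math.sqrt(nugget_var) * rng.standard_normal(n) if nugget_var > 0 else 0.0
    )
    deprivation = np.asarray(z_spatial + z_nugget, dtype=float)
    # standardize the cross-section to exact mean 0 / sd factor_sd: the
    # spatial process makes the realized mean of a single draw wander, which
    # would shift every indicator's marginal rate away from its calibration
    # target; the spatial correlation structure is unaffected
    if config.factor_sd > 0 and n > 1 and deprivation.std() > 0:
        deprivation = (
            (deprivation - deprivation.mean()) / deprivation.std() * config.factor_sd
        )
    if config.factor_sd == 0:
        deprivation = np.zeros(n)

    return pd.DataFrame({
        "cluster_id": [f"CL{i + 1:05d}" for i in range(n)],
        "region_id": region,
        "country_id": country,
        "true_lon": lon,
        "true_lat": lat,
        "urban": urban.astype(int),
        "deprivation": deprivation,
    })


# ---------------------------------------------------------------------------
# Households
# ---------------------------------------------------------------------------

def _liability(z: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    return z + noise_sd * rng.standard_normal(z.shape)


def _threshold(rate: float, total_sd: float) -> float:
    """Liability cut so that P(liability > cut) = rate under N(0, total_sd^2)."""
    if rate <= 0:
        return np.inf
    if rate >= 1:
        return -np.inf
    if total_sd == 0:
        # degenerate liability: everyone is 0 below, 1 above; put the cut at 0
        # so rate >= 0.5 marks everyone deprived (liability 0 > -eps)
        return 0.0 if rate < 0.5 else -np.inf
    return float(ndtri(1.0 - rate)) * total_sd


def generate_households(field: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Draw household microdata from the latent cluster field.

    Each indicator is a monotone stochastic function of cluster deprivation:
    binary indicators arise by thresholding the household liability
    (cluster deprivation + Gaussian household noise), so each marginal rate
    equals its calibration target in expectation; the toilet-sharing count
    is 1 + Poisson with log-mean increasing in the liability (among
    sharers); persons per room follows a lognormal target increasing in the
    liability, realized by choosing the number of sleeping rooms.
    """
    if len(field) == 0:
        raise ConfigurationError("latent field is empty; generate clusters first")
    rng = _child_rng(config, "households")
    cal = config.indicator_calibration
    m = config.households_per_cluster
    n = len(field) * m

    z = np.repeat(field["deprivation"].to_numpy(), m)
    cluster_id = np.repeat(field["cluster_id"].to_numpy(), m)
    noise = config.indicator_noise_sd
    total_sd = math.hypot(config.factor_sd, noise)

    def binary(rate: float) -> np.ndarray:
        return (_liability(z, noise, rng) > _threshold(rate, total_sd)).astype(int)

    shares_toilet = binary(cal["shared_toilet_rate"])
    water_public = binary(cal["public_water_rate"])
    no_mobile = binary(cal["no_mobile_rate"])
    no_vehicle = binary(cal["no_vehicle_rate"])

    # count of other households sharing the toilet, increasing in deprivation
    u = _liability(z, noise, rng)
    u = u / total_sd if total_sd > 0 else np.zeros(n)
    lam0 = max(cal["mean_extra_sharers"] - 1.0, 0.0) * _SHARERS_SELECTION_FACTOR
    extra = rng.poisson(lam0 * np.exp(_SHARERS_SLOPE * u))
    toilet_sharing_count = shares_toilet * (1 + extra)

    # household size independent of deprivation; crowding via room count
    n_members = 1 + rng.poisson(max(cal["household_size_mean"] - 1.0, 0.0), size=n)
    u_ppr = _liability(z, noise, rng)
    u_ppr = u_ppr / total_sd if total_sd > 0 else np.zeros(n)
    target_mean = cal["persons_per_room_mean"] / _PPR_ROUNDING_FACTOR
    # lognormal(mu, slope) with mean target_mean: mu = log(target) - slope^2/2
    mu = math.log(target_mean) - _PPR_SLOPE ** 2 / 2.0
    ppr_target = np.exp(mu + _PPR_SLOPE * u_ppr)
    n_rooms = np.maximum(1, np.rint(n_members / ppr_target).astype(int))

    sample_weight = rng.lognormal(mean=0.0, sigma=config.weight_log_sd, size=n)

    return pd.DataFrame({
        "household_id": [f"HH{i + 1:07d}" for i in range(n)],
        "cluster_id": cluster_id,
        "sample_weight": sample_weight,
        "toilet_sharing_count": toilet_sharing_count,
        "water_public": water_public,
        "n_members": n_members,
        "n_sleeping_rooms": n_rooms,
        "has_mobile": 1 - no_mobile,
        "has_vehicle": 1 - no_vehicle,
    })


# ---------------------------------------------------------------------------
# Coordinate displacement
# ---------------------------------------------------------------------------

def _destination(lon: np.ndarray, lat: np.ndarray, bearing: np.ndarray,
                 dist_km: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spherical direct problem: point at great-circle distance along bearing."""
    lat1 = np.radians(lat)
    lon1 = np.radians(lon)
    d = dist_km / EARTH_RADIUS_KM
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(bearing)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(bearing) * np.sin(d) * np.cos(lat1),
        np.cos(d) - np.sin(lat1) * np.sin(lat2),
    )
    return np.degrees(lon2), np.degrees(lat2)


def displace_coordinates(field: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """DHS-style anonymizing displacement of cluster coordinates.

    Uniform random bearing; distance uniform on [0, radius] with radius
    2 km for urban and 5 km for rural clusters by default.  Returns the
    public cluster table (cluster_id, lon, lat, urban, region_id,
    country_id); true coordinates stay in the latent field for oracle use.
    """
    rng = _child_rng(config, "displacement")
    n = len(field)
    radius = np.where(
        field["urban"].to_numpy() == 1,
        config.displacement_urban_km,
        config.displacement_rural_km,
    )
    bearing = rng.uniform(0.0, 2.0 * math.pi, n)
    dist = rng.uniform(0.0, 1.0, n) * radius
    lon, lat = _destination(
        field["true_lon"].to_numpy(), field["true_lat"].to_numpy(), bearing, dist
    )
    return pd.DataFrame({
        "cluster_id": field["cluster_id"].to_numpy(),
        "lon": lon,
        "lat": lat,
        "urban": field["urban"].to_numpy(),
        "region_id": field["region_id"].to_numpy(),
        "country_id": field["country_id"].to_numpy(),
    })


# ---------------------------------------------------------------------------
# Density raster
# ---------------------------------------------------------------------------

def generate_density_raster(config: SyntheticConfig,
                            field: pd.DataFrame | None = None) -> DensityRaster:
    """Smooth random density surface over the region bounding box.

    A coarse Gaussian field is bilinearly upsampled, urban clusters add
    local bumps, and the result is mapped onto ``density_range``
    (log-uniformly when the minimum is positive).  Values therefore always
    lie inside the configured range, and a collapsed range yields a
    constant raster.
    """
    rng = _child_rng(config, "raster")
    lon_min, lat_min, lon_max, lat_max = config.bounding_box()
    cell = config.grid_cell_size
    # margin so clusters displaced out of the region box stay on the raster
    # (1 degree of latitude ~ 111 km)
    max_disp_deg = max(config.displacement_urban_km,
                       config.displacement_rural_km) / 111.0 * 1.5
    pad = int(math.ceil(max_disp_deg / cell)) + 1
    lon_min -= pad * cell
    lat_min -= pad * cell
    lon_max += pad * cell
    n_cols = int(math.ceil((lon_max - lon_min) / cell))
    n_rows = int(math.ceil((lat_max - lat_min) / cell)) + pad
    origin_lat = lat_min + n_rows * cell  # pad northwards so the box is covered

    coarse = rng.standard_normal((max(n_rows // 8, 2) + 1, max(n_cols // 8, 2) + 1))
    ri = np.linspace(0, coarse.shape[0] - 1, n_rows)
    ci = np.linspace(0, coarse.shape[1] - 1, n_cols)
    r0 = np.floor(ri).astype(int).clip(0, coarse.shape[0] - 2)
    c0 = np.floor(ci).astype(int).clip(0, coarse.shape[1] - 2)
    fr = (ri - r0)[:, None]
    fc = (ci - c0)[None, :]
    f = (
        coarse[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
        + coarse[np.ix_(r0 + 1, c0)] * fr * (1 - fc)
        + coarse[np.ix_(r0, c0 + 1)] * (1 - fr) * fc
        + coarse[np.ix_(r0 + 1, c0 + 1)] * fr * fc
    )

    if field is not None and len(field) and field["urban"].sum() > 0:
        lons = lon_min + (np.arange(n_cols) + 0.5) * cell
        lats = origin_lat - (np.arange(n_rows) + 0.5) * cell
        scale = 3.0 * cell
        for _, cl in field[field["urban"] == 1].iterrows():
            d2 = ((lons[None, :] - cl.true_lon) ** 2
                  + (lats[:, None] - cl.true_lat) ** 2)
            f += 2.0 * np.exp(-d2 / (2.0 * scale ** 2))

    lo, hi = config.density_range
    if hi == lo:
        values = np.full((n_rows, n_cols), float(lo))
    else:
        f01 = (f - f.min()) / (f.max() - f.min())
        if lo > 0:
            values = np.exp(math.log(lo) + f01 * (math.log(hi) - math.log(lo)))
        else:
            values = lo + f01 * (hi - lo)
    return DensityRaster(origin_lon=lon_min, origin_lat=origin_lat,
                         cell_size=cell, values=values)


# ---------------------------------------------------------------------------
# Caseloads
# ---------------------------------------------------------------------------

def generate_caseloads(regional_risk: pd.DataFrame,
                       config: SyntheticConfig) -> pd.DataFrame:
    """Cumulative epidemic caseloads per region.

    ``regional_risk`` needs columns region_id and risk (latent regional
    deprivation).  Cases are Poisson with
    log-rate = log(baseline) + caseload_effect * standardized risk + frailty,
    where the lognormal region frailty (sd ``caseload_dispersion_sd``)
    captures everything besides infrastructure that drives real caseloads
    (importation, testing, age structure...).
    """
    if regional_risk["region_id"].duplicated().any():
        raise ConfigurationError("one latent risk value per region is required")
    rng = _child_rng(config, "caseloads")
    risk = regional_risk["risk"].to_numpy(dtype=float)
    sd = risk.std()
    risk_std = (risk - risk.mean()) / sd if sd > 0 else np.zeros_like(risk)
    frailty = config.caseload_dispersion_sd * rng.standard_normal(len(risk))
    lam = np.exp(math.log(config.caseload_baseline)
                 + config.caseload_effect * risk_std + frailty)
    cases = rng.poisson(lam)
    return pd.DataFrame({
        "region_id": regional_risk["region_id"].to_numpy(),
        "cumulative_cases": cases.astype(int),
    })


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """All tables of one simulated survey world."""

    config: SyntheticConfig
    field: pd.DataFrame        # latent truth, per cluster
    households: pd.DataFrame
    clusters: pd.DataFrame     # public (displaced) coordinates
    raster: DensityRaster
    caseloads: pd.DataFrame
    regions: pd.DataFrame      # rectangle bounds per region

    @property
    def regional_truth(self) -> pd.DataFrame:
        """Mean latent deprivation per region (the recovery target)."""
        t = (self.field.groupby("region_id", as_index=False)["deprivation"]
             .mean().rename(columns={"deprivation": "true_deprivation"}))
        return t


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generators in their fixed order and bundle the outputs."""
    field = generate_latent_field(config)
    households = generate_households(field, config)
    clusters = displace_coordinates(field, config)
    raster = generate_density_raster(config, field)
    risk = (field.groupby("region_id", as_index=False)["deprivation"].mean()
            .rename(columns={"deprivation": "risk"}))
    caseloads = generate_caseloads(risk, config)
    return SyntheticDataset(
        config=config, field=field, households=households, clusters=clusters,
        raster=raster, caseloads=caseloads, regions=config.region_boxes(),
    )
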