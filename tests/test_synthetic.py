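import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdindex.errors import ConfigurationError
from pdindex.synthetic import (
    SyntheticConfig,
    displace_coordinates,
    generate_caseloads,
    generate_density_raster,
    generate_households,
    generate_latent_field,
    simulate,
)


def haversine_km(lon1, lat1, lon2, lat2):
    R = 6371.0088
    p1, p2 = np.radians(lat1), np.radians(lat2)
    a = (np.sin((p2 - p1) / 2) ** 2
         + np.cos(p1) * np.cos(p2) * np.sin(np.radians(lon2 - lon1) / 2) ** 2)
    return 2 * R * np.arcsin(np.sqrt(a))


@pytest.mark.parametrize("bad", [
    {"n_regions": 0}, {"clusters_per_region": -1}, {"households_per_cluster": 0},
    {"grid_cell_size": 0.0}, {"factor_sd": -1.0}, {"nugget_share": 1.5},
    {"density_range": (10.0, 1.0)}, {"displacement_urban_km": -2.0},
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ConfigurationError):
        SyntheticConfig(**bad)


def test_full_generation_is_deterministic(small_config):
    a, b = simulate(small_config), simulate(small_config)
    pd.testing.assert_frame_equal(a.field, b.field)
    pd.testing.assert_frame_equal(a.households, b.households)
    pd.testing.assert_frame_equal(a.clusters, b.clusters)
    pd.testing.assert_frame_equal(a.caseloads, b.caseloads)
    np.testing.assert_array_equal(a.raster.values, b.raster.values)


def test_latent_field_structure(small_config):
    field = generate_latent_field(small_config)
    assert len(field) == small_config.n_regions * small_config.clusters_per_region
    # clusters inside their region rectangles
    merged = field.merge(small_config.region_boxes(), on="region_id")
    assert (merged.true_lon >= merged.lon_min).all()
    assert (merged.true_lon <= merged.lon_max).all()
    assert (merged.true_lat >= merged.lat_min).all()
    assert (merged.true_lat <= merged.lat_max).all()
    # calibrated cross-section: mean ~ 0, sd ~ factor_sd
    assert abs(field.deprivation.mean()) < 1e-10
    assert field.deprivation.std(ddof=0) == pytest.approx(
        small_config.factor_sd, rel=1e-10)


def test_zero_factor_sd_gives_all_zero_deprivation():
    cfg = SyntheticConfig(seed=2, n_regions=4, factor_sd=0.0)
    field = generate_latent_field(cfg)
    assert (field.deprivation == 0).all()


def test_zero_range_deprivation_is_spatially_uncorrelated():
    """At range 0 the spatial kernel degenerates: nearby clusters share nothing."""
    cfg = SyntheticConfig(seed=5, n_regions=16, clusters_per_region=25,
                          factor_spatial_range=0.0)
    field = generate_latent_field(cfg)
    # correlation between each cluster and its nearest neighbour
    xy = field[["true_lon", "true_lat"]].to_numpy()
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)
    r = stats.pearsonr(field.deprivation, field.deprivation.to_numpy()[nn]).statistic
    assert abs(r) < 3.0 / np.sqrt(len(field))  # Monte-Carlo null bound


def test_positive_range_induces_spatial_correlation():
    cfg = SyntheticConfig(seed=5, n_regions=16, clusters_per_region=25,
                          factor_spatial_range=2.0, nugget_share=0.0)
    field = generate_latent_field(cfg)
    xy = field[["true_lon", "true_lat"]].to_numpy()
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)
    r = stats.pearsonr(field.deprivation, field.deprivation.to_numpy()[nn]).statistic
    assert r > 0.5


def test_households_require_nonempty_field(small_config):
    with pytest.raises(ConfigurationError):
        generate_households(small_config.region_boxes().iloc[:0], small_config)


def test_zero_noise_constant_cluster_gives_identical_binaries():
    cfg = SyntheticConfig(seed=3, n_regions=2, clusters_per_region=4,
                          households_per_cluster=30, indicator_noise_sd=0.0)
    field = generate_latent_field(cfg)
    hh = generate_households(field, cfg)
    for _, g in hh.groupby("cluster_id"):
        for col in ("water_public", "has_mobile", "has_vehicle"):
            assert g[col].nunique() == 1
        assert ((g.toilet_sharing_count > 0).nunique()) == 1


def test_indicators_are_monotone_in_deprivation_deciles():
    """Decile means of every deprivation-coded indicator rise with the factor."""
    cfg = SyntheticConfig(seed=3, n_regions=30, clusters_per_region=20,
                          households_per_cluster=50, indicator_noise_sd=0.0)
    field = generate_latent_field(cfg)
    hh = generate_households(field, cfg).merge(
        field[["cluster_id", "deprivation"]], on="cluster_id")
    hh["decile"] = pd.qcut(hh.deprivation, 10, labels=False)
    hh["ppr"] = hh.n_members / np.maximum(hh.n_sleeping_rooms, 1)
    hh["no_ict"] = 1 - hh.has_mobile
    hh["no_vehicle"] = 1 - hh.has_vehicle
    means = hh.groupby("decile")[
        ["toilet_sharing_count", "water_public", "ppr", "no_ict", "no_vehicle"]
    ].mean()
    for col in means.columns:
        assert (np.diff(means[col].to_numpy()) >= -1e-9).all(), col


def test_household_record_invariants(small_dataset):
    hh = small_dataset.households
    assert (hh.sample_weight > 0).all()
    assert (hh.n_members >= 1).all()
    assert (hh.toilet_sharing_count >= 0).all()
    assert hh.water_public.isin([0, 1]).all()
    assert hh.has_mobile.isin([0, 1]).all()
    assert hh.has_vehicle.isin([0, 1]).all()


def test_displacement_zero_radius_is_identity(small_config):
    cfg = dataclasses.replace(small_config, displacement_urban_km=0.0,
                              displacement_rural_km=0.0)
    field = generate_latent_field(cfg)
    pub = displace_coordinates(field, cfg)
    np.testing.assert_allclose(pub.lon, field.true_lon, atol=1e-12)
    np.testing.assert_allclose(pub.lat, field.true_lat, atol=1e-12)


def test_displacement_within_configured_radius(small_dataset, small_config):
    field, pub = small_dataset.field, small_dataset.clusters
    d = haversine_km(field.true_lon, field.true_lat, pub.lon, pub.lat)
    rmax = np.where(field.urban == 1, small_config.displacement_urban_km,
                    small_config.displacement_rural_km)
    assert (d <= rmax + 1e-9).all()
    assert (d > 0).all()  # displacement actually happened


def test_density_raster_contract(small_config, small_dataset):
    raster = small_dataset.raster
    lo, hi = small_config.density_range
    assert raster.values.min() >= lo - 1e-9
    assert raster.values.max() <= hi + 1e-9
    assert raster.cell_size == small_config.grid_cell_size
    # grid covers the full region bounding box
    lon_min, lat_min, lon_max, lat_max = small_config.bounding_box()
    ext = raster.extent
    assert ext[0] <= lon_min and ext[1] <= lat_min
    assert ext[2] >= lon_max and ext[3] >= lat_max


def test_collapsed_density_range_gives_constant_raster():
    cfg = SyntheticConfig(seed=1, n_regions=4, density_range=(250.0, 250.0))
    raster = generate_density_raster(cfg, generate_latent_field(cfg))
    np.testing.assert_array_equal(raster.values, 250.0)


def test_caseloads_null_and_strong_effect():
    regions = [f"R{i}" for i in range(50)]
    rng = np.random.default_rng(99)
    risk = pd.DataFrame({"region_id": regions, "risk": rng.standard_normal(50)})

    # null: no systematic association (MC null bound over 40 replicates)
    null_rhos = [
        stats.spearmanr(
            risk.risk,
            generate_caseloads(
                risk, SyntheticConfig(seed=s, caseload_effect=0.0)
            ).cumulative_cases,
        ).statistic
        for s in range(40)
    ]
    assert abs(np.mean(null_rhos)) < 0.1

    # strong effect: rank correlation above 0.8 on average
    # (bound fixed by a 500-replicate Monte-Carlo oracle: mean 0.88)
    strong = [
        stats.spearmanr(
            risk.risk,
            generate_caseloads(
                risk, SyntheticConfig(seed=s, caseload_effect=2.0)
            ).cumulative_cases,
        ).statistic
        for s in range(40)
    ]
    assert np.mean(strong) > 0.8
    assert (pd.concat([generate_caseloads(risk, SyntheticConfig(seed=7))
                       for _ in range(2)]).cumulative_cases >= 0).all()


def test_caseloads_require_unique_regions():
    risk = pd.DataFrame({"region_id": ["R1", "R1"], "risk": [0.0, 1.0]})
    with pytest.raises(ConfigurationError):
        generate_caseloads(risk, SyntheticConfig(seed=0))


def test_regional_truth_matches_field_means(small_dataset):
    truth = small_dataset.regional_truth
    manual = small_dataset.field.groupby("region_id")["deprivation"].mean()
    np.testing.assert_allclose(
        truth.set_index("region_id")["true_deprivation"], manual)
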