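import numpy as np
import pandas as pd
import pytest

from pdindex.pipeline import run_study
from pdindex.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def small_config():
    """Compact but fully structured world: 6 regions x 10 clusters x 20 hh."""
    return SyntheticConfig(seed=11, n_regions=6, clusters_per_region=10,
                           households_per_cluster=20)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One end-to-end run at the default study conditions (30x20x25)."""
    return run_study(SyntheticConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def two_household_tables():
    """Minimal scores/households/clusters triple for aggregation algebra."""
    def make(scores, weights, densities=None, cluster_ids=("A", "B")):
        n = len(scores)
        ids = [f"h{i}" for i in range(n)]
        score_df = pd.DataFrame({"household_id": ids, "score": scores})
        hh = pd.DataFrame({
            "household_id": ids,
            "cluster_id": list(cluster_ids)[:n],
            "sample_weight": weights,
        })
        clusters = pd.DataFrame({
            "cluster_id": sorted(set(cluster_ids[:n])),
            "lon": np.linspace(0.25, 0.75, len(set(cluster_ids[:n]))),
            "lat": np.linspace(0.25, 0.75, len(set(cluster_ids[:n]))),
            "region_id": "R1",
            "country_id": "C1",
        })
        return score_df, hh, clusters
    return make
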