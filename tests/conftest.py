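import numpy as np
import pandas as pd
import pytest

import pcnmkit as pk


@pytest.fixture(scope="session")
def grid_sites():
    return pk.make_grid_sites(6, 6, 1000.0)


@pytest.fixture(scope="session")
def grid_dmat(grid_sites):
    return pk.pairwise_distance_matrix(grid_sites)


@pytest.fixture(scope="session")
def grid_eigenmap(grid_sites):
    return pk.eigenmap_for_sites(grid_sites)


@pytest.fixture(scope="session")
def transect_eigenmap():
    sites = pd.DataFrame({
        "site_id": [f"t{i:02d}" for i in range(50)],
        "x": np.arange(50) * 1000.0,
        "y": np.zeros(50),
    })
    return sites, pk.eigenmap_for_sites(sites)


def random_sites(n, seed, extent=100_000.0):
    return pk.make_random_sites(n, extent=extent, seed=seed, aspect=1.0)


@pytest.fixture(scope="session")
def small_random_sites():
    return random_sites(10, seed=11)
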