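import numpy as np
import pandas as pd
import pytest

import phylogradient as pg
from phylogradient.grid import PresenceMatrix, SiteGrid


@pytest.fixture
def toy():
    """The bundled hand-checkable worked example."""
    return pg.make_toy_fixture()


@pytest.fixture(scope="session")
def nested_dataset():
    """Small nested-mode synthetic study reused across tests."""
    return pg.simulate_dataset(pg.SyntheticConfig(seed=2, n_species=80))


def make_random_instance(seed, n_species=10, n_cells=20, occupancy=0.35):
    """Random small tree + presence matrix for brute-force oracles."""
    rng = np.random.default_rng(seed)
    cfg = pg.SyntheticConfig(seed=seed, n_species=n_species,
                             tree_model="yule")
    tree = pg.simulate_tree(cfg)
    while True:
        occ = (rng.random((n_cells, n_species)) < occupancy).astype(np.int8)
        if (occ.sum(axis=0) > 0).all():
            break
    lat = np.sort(rng.uniform(8.2, 18.8, n_cells))
    grid = SiteGrid(
        pd.DataFrame(
            {"lat": lat, "lon": np.full(n_cells, 75.5)},
            index=pd.Index([f"cell{i:03d}" for i in range(n_cells)],
                           name="cell"),
        )
    )
    pm = PresenceMatrix(
        pd.DataFrame(occ, index=grid.cells, columns=tree.tip_labels), grid
    )
    return tree, pm


@pytest.fixture
def random_instance():
    return make_random_instance(7)
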