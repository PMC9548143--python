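import numpy as np
import pytest
from hypothesis import settings

import temcn
from temcn import aggregation_stats as agg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_grid():
    """6x6 cells over a mid-China window."""
    return temcn.GridSpec(26.0, 38.0, 100.0, 112.0, 2.0)


@pytest.fixture(scope="session")
def china():
    return temcn.china_grid(2.0)


@pytest.fixture(scope="session")
def default_forcing(china):
    return temcn.generate_climate(china, "default", 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world(small_grid):
    """Generated inputs on the small grid, shared by the slower tests."""
    grid = small_grid
    areas = agg.grid_cell_areas(grid)
    return {
        "grid": grid,
        "areas": areas,
        "forcing": temcn.generate_climate(grid, "default", 11),
        "co2": temcn.generate_co2_series(),
        "land": temcn.generate_land_cover(grid, "default", 11, areas),
        "land_static": temcn.generate_land_cover(grid, "static", 11, areas),
        "soil": temcn.generate_soil(grid, 11),
    }
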