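import numpy as np
import pytest

import biomeshift as bs


@pytest.fixture
def small_grid() -> bs.GridDescriptor:
    return bs.GridDescriptor(rows=30, cols=40)


@pytest.fixture(scope="session")
def biome_small():
    """A 16k-pixel rainfall-axis biome: config, driver field, tree cover."""
    cfg = bs.SyntheticBiomeConfig(grid_shape=(100, 160), seed=11)
    axis = bs.generate_axis_field(cfg)
    tree = bs.generate_tree_cover(cfg, axis)
    return cfg, axis, tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_cube(values, years, grid):
    return bs.MonthlyClimateCube(values=values, years=np.asarray(years), grid=grid)
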