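import numpy as np
import pytest

from dugongrisk.geo import Grid, GridTransform
from dugongrisk.synthetic import ScenarioConfig, generate_scenario


def make_grid(values, cell=1.0, mask=None, crs_tag="planar-km"):
    values = np.asarray(values, dtype=float)
    rows, _cols = values.shape
    transform = GridTransform(x0=0.0, y0=rows * cell, cell_w=cell, cell_h=cell)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return Grid(values=values, transform=transform, mask=np.asarray(mask, dtype=bool), crs_tag=crs_tag)


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture(scope="session")
def default_scenario():
    """The default 100x100 study scenario at seed 0."""
    return generate_scenario(ScenarioConfig(seed=0))


@pytest.fixture(scope="session")
def small_scenario():
    """A fast 50x50 scenario for pipeline-level tests."""
    return generate_scenario(ScenarioConfig(seed=1, grid_shape=(50, 50), n_presence=40, survey_n=10))
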