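import numpy as np
import pytest

from sympatry.grids import GridGeometry
from sympatry.simulate import SyntheticScenario, generate_landscape


@pytest.fixture(scope="session")
def geometry():
    # 48 x 48 cells: divisible by the 8 CV bins so equal-count binning is exact
    return GridGeometry(0.0, 0.0, 30.0, 48, 48)


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(rng_seed=3)


@pytest.fixture(scope="session")
def landscape(scenario, geometry):
    return generate_landscape(scenario, geometry, np.random.default_rng(3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
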