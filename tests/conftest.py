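import numpy as np
import pytest

from sedsim import hexgrid, simulator, synthetic


@pytest.fixture(scope="session")
def grid_small():
    """Coarse 362-cell grid for geometry and growth tests."""
    return hexgrid.build_geodesic_grid(6)


@pytest.fixture(scope="session")
def planet_coarse():
    """Default seasonal planet on a 1442-cell grid."""
    return synthetic.make_planet(synthetic.fixture_spec("default", frequency=12))


@pytest.fixture(scope="session")
def scape_coarse(planet_coarse):
    return synthetic.planet_energyscape(planet_coarse)


@pytest.fixture(scope="session")
def params_coarse():
    """Option counts and range sizes scaled to the coarse grid."""
    return simulator.SimParams(
        n_options={"WH": 40, "EH": 60}, range_sizes={"WH": 9, "EH": 12}, seed=11
    )


@pytest.fixture(scope="session")
def assemblage_coarse(scape_coarse, params_coarse):
    return simulator.run_simulation(scape_coarse, params_coarse)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
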