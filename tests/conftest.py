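import numpy as np
import pytest

from movemix import (
    CategoricalRaster,
    IndividualParams,
    ModelConstants,
    design_matrix,
    generate_synthetic_raster,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def raster() -> CategoricalRaster:
    """Patchy 60x60 raster, 2 m cells, roughly equal category cover."""
    return generate_synthetic_raster(60, 60, cell_size=2.0, seed=101)


@pytest.fixture(scope="session")
def big_raster() -> CategoricalRaster:
    """1.5 km x 1.5 km landscape: large enough that a movement-state walk
    (sigma1 ~ 25 m) almost never hits the boundary over hundreds of days."""
    return generate_synthetic_raster(150, 150, cell_size=10.0, seed=102)


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def known_params() -> IndividualParams:
    """A movement-heavy individual with known parameters for recovery."""
    return IndividualParams(
        beta=np.array([0.3, -0.2, 0.1, -0.4]),
        gamma=0.6,
        theta=np.pi,
        sigma1_sq=625.0,  # sigma1 = 25 m
    )


@pytest.fixture(scope="session")
def simulated_individual(big_raster, constants, known_params):
    """One long (T=300) simulated trajectory with its design matrix."""
    traj, z = simulate_trajectory(
        known_params, big_raster, T=300, start=(750.0, 750.0),
        constants=constants, seed=42,
    )
    return traj, z, design_matrix(big_raster, traj)
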