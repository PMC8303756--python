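import pytest

from spheroidsim.params import ModelParameters
from spheroidsim.solver import MappedGrid, SolverConfig, simulate


@pytest.fixture(scope="session")
def set1_params() -> ModelParameters:
    """First reference comparison set: eta* = 1.6, C0/Ci = 1.5, K* = 1,
    R0 = 0.01 cm."""
    return ModelParameters.from_dimensionless(
        K_star=1.0, eta_star=1.6, C0_over_Ci=1.5, R0=0.01
    )


@pytest.fixture(scope="session")
def set2_params() -> ModelParameters:
    """Second reference comparison set: eta* = 2, C0/Ci = 2, R0 = 0.02 cm."""
    return ModelParameters.from_dimensionless(
        K_star=1.0, eta_star=2.0, C0_over_Ci=2.0, R0=0.02
    )


@pytest.fixture(scope="session")
def coarse_grid() -> MappedGrid:
    return MappedGrid(n_nodes=51)


@pytest.fixture(scope="session")
def coarse_cfg() -> SolverConfig:
    return SolverConfig(dt=1e-3)


@pytest.fixture(scope="session")
def cn_set1(set1_params):
    """Default-resolution CN trajectory of set 1, shared across tests."""
    return simulate(set1_params)


@pytest.fixture(scope="session")
def cn_set2(set2_params):
    return simulate(set2_params)
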