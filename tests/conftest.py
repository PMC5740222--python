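import numpy as np
import pytest

from mpetsim import (TransferModel, default_waveforms,
                     effective_permeability, generate_shell_mesh,
                     load_parameters, steady_territory_fluxes,
                     territory_fluxes)


@pytest.fixture(scope="session")
def shell_mesh():
    """Small labeled shell at human ventricle-to-cortex scale."""
    return generate_shell_mesh(0.03, 0.07, 1.0, resolution=(3, 3))


@pytest.fixture(scope="session")
def coarse_shell():
    return generate_shell_mesh(0.03, 0.07, 1.0, resolution=(2, 2))


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def keff(params, shell_mesh):
    return effective_permeability(params, None, shell_mesh)


@pytest.fixture(scope="session")
def transfer_model(params):
    return TransferModel.from_parameters(params)


@pytest.fixture(scope="session")
def brain_fluxes(coarse_shell):
    """Territory fluxes bound to the coarse shell used by solver tests."""
    waves = default_waveforms("control", "high", n_cycles=2)
    return territory_fluxes(waves, coarse_shell)


@pytest.fixture(scope="session")
def steady_fluxes(coarse_shell):
    waves = default_waveforms("control", "high", n_cycles=2)
    return steady_territory_fluxes(waves, coarse_shell)
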