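import numpy as np
import pytest

from angiosim import Grid1D, InitialConditions, ModelParameters, SystemState, tumor_factor


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def grid():
    return Grid1D(L_f=1.0, M=8)


@pytest.fixture
def profile(grid, params):
    return tumor_factor(grid, params.eps, params.alpha4)


@pytest.fixture
def zero_taf_profile(grid, params):
    """Profile with the tumor factor switched off (T = phi = 0)."""
    import dataclasses

    base = tumor_factor(grid, params.eps, params.alpha4)
    z = np.zeros(grid.n_nodes)
    return dataclasses.replace(base, T=z, phi=z, dphi_dx=z)


@pytest.fixture
def test2_initial(grid):
    from angiosim import build_initial_state

    return build_initial_state(InitialConditions(), grid)


def random_state(grid, rng, low=0.0, high=1.0):
    return SystemState(rng.uniform(low, high, size=(5, grid.n_nodes)))
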