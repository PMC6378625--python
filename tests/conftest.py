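import numpy as np
import pytest

from ionfv import ModelParams, State, build_rectangular_mesh


@pytest.fixture
def two_cell_mesh():
    """Two half-unit cells on the unit square; the shared edge has
    m(sigma) = 1, d_sigma = 0.5, tau_sigma = 2."""
    return build_rectangular_mesh(2, 1)


@pytest.fixture
def single_cell_mesh():
    return build_rectangular_mesh(1, 1)


def drift_free_params(n=1, truncated=False):
    return ModelParams(n=n, D=np.ones(n), z=np.zeros(n),
                       drift_enabled=False, truncation_enabled=truncated)


def two_cell_state(u_pairs, phi=(0.0, 0.0)):
    """State on the 2x1 mesh from per-species (u_K, u_L) pairs."""
    u = np.array(u_pairs, dtype=float)
    return State(u, np.array(phi, dtype=float))
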