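import numpy as np
import pytest

import glymphuq as g


@pytest.fixture(scope="session")
def brain_mesh():
    """Coarse synthetic brain-like geometry (default parameters)."""
    return g.build_synthetic_brain()


@pytest.fixture(scope="session")
def unit_cube():
    return g.build_box_mesh((1.0, 1.0, 1.0), (4, 4, 4))


@pytest.fixture(scope="session")
def small_sampler():
    """Matern sampler on a small box resolving lambda = 0.01 m at lambda/3."""
    spec = g.MaternSpec(0.01, box_origin=(0, 0, 0), box_extent=(0.06, 0.06, 0.06),
                        grid_spacing=0.01 / 3)
    return g.MaternFieldSampler(spec)


@pytest.fixture(scope="session")
def baseline_series(brain_mesh):
    """24 h constant-diffusivity reference run, shared across tests."""
    coeffs = g.CoefficientSample(1.2e-10, None, 0.0, seed=0, model="baseline")
    return g.solve_transport(g.TransportProblem(brain_mesh, coeffs))


def rng(seed=0):
    return np.random.default_rng(seed)
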