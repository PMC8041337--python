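import numpy as np
import pytest

from sfcoupling.beamformer import build_source_grid
from sfcoupling.synthetic import (make_ellipsoid_mask, make_sensor_shell,
                                  make_symmetric_space, make_toy_leadfield)

# bivariate VAR(2): two damped oscillators, channel 0 -> channel 1
VAR_COEFFS = np.array([
    [[0.55, 0.00],
     [0.25, 0.55]],
    [[-0.80, 0.00],
     [0.00, -0.80]],
])
VAR_NOISE = np.eye(2)
VAR_FS = 120.0


@pytest.fixture(scope="session")
def toy_space():
    return make_symmetric_space((16, 16, 16), 2.0)


@pytest.fixture(scope="session")
def toy_mask(toy_space):
    return make_ellipsoid_mask(toy_space)


@pytest.fixture(scope="session")
def toy_grid(toy_mask):
    return build_source_grid(toy_mask, spacing=5.0)


@pytest.fixture(scope="session")
def toy_leadfield(toy_grid):
    sensors = make_sensor_shell(16, radius=45.0)
    return make_toy_leadfield(toy_grid.points, sensors)


@pytest.fixture(scope="session")
def var_fixture():
    return VAR_COEFFS, VAR_NOISE, VAR_FS
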