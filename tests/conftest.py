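import numpy as np
import pytest

from gammabeam.forward import (HeadModel, build_sensor_array,
                               build_source_grid, lead_field_matrix)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def sensors(head):
    # small array keeps forward/inverse tests fast; geometry is identical
    # in kind to the full 248-channel default
    return build_sensor_array(32, head=head)


@pytest.fixture(scope="session")
def coarse_grid(head):
    return build_source_grid(15.0, head)


@pytest.fixture(scope="session")
def coarse_leadfield(coarse_grid, sensors, head):
    return lead_field_matrix(coarse_grid, sensors, head)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
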