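import numpy as np
import pytest

from squeezelab import DeviceGeometry, synthgen


@pytest.fixture(scope="session")
def geometry():
    return DeviceGeometry()


@pytest.fixture(scope="session")
def small_plate():
    """A compact rendered plate shared by segmentation tests."""
    spec = synthgen.PlateSpec(seed=2)
    wells, truth = synthgen.generate_if_plate(spec)
    return spec, wells, truth


@pytest.fixture(scope="session")
def transit_sequence(geometry):
    params = synthgen.SqueezeModelParams(seed=3)
    stack, truth = synthgen.generate_transit_sequence(geometry, params, 20)
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
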