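import numpy as np
import pytest

import oddphot as op
from oddphot.synth import NOISE_FREE


@pytest.fixture(scope="session")
def kernel():
    return op.KernelParams()


@pytest.fixture(scope="session")
def sensor():
    return op.SensorParams()


@pytest.fixture(scope="session")
def noise_free():
    return NOISE_FREE


@pytest.fixture(scope="session")
def simple_recording_noise_free(kernel, sensor, noise_free):
    """10 x 6-s white-noise presentations, rendered without noise."""
    seq = op.gen_simple(6.0, 80.0, 10, 3.0)
    rec, truth = op.render_recording(
        seq, kernel=kernel, sensor=sensor, noise=noise_free, seed=11
    )
    return rec, truth


@pytest.fixture(scope="session")
def simple_recording_noisy(kernel, sensor):
    seq = op.gen_simple(6.0, 80.0, 10, 3.0)
    rec, truth = op.render_recording(seq, kernel=kernel, sensor=sensor, seed=12)
    return rec, truth
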