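import numpy as np
import pytest

from hybrot.core import Raster, make_geometry


@pytest.fixture(scope="session")
def geometry():
    return make_geometry("mcs_8x8")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_raster(geometry, rng, n_spikes=1000, duration=10.0):
    """A sorted random raster over the recording electrodes."""
    electrodes = rng.choice(geometry.recording_electrodes, size=n_spikes)
    times = np.sort(rng.uniform(0, duration, size=n_spikes))
    return Raster(
        duration=duration,
        electrodes=np.array(electrodes, dtype=object),
        times=times,
        geometry=geometry,
    )


@pytest.fixture
def small_raster(geometry, rng):
    return random_raster(geometry, rng, n_spikes=200, duration=5.0)
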