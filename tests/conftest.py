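import numpy as np
import pytest

from flimtrack.config import AcquisitionConfig, rapid_flim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rapid():
    """Rapid-detector acquisition at 40 MHz, 2 ns dead time."""
    return rapid_flim()


@pytest.fixture
def clean_acq():
    """Idealized acquisition: no dead time, no IRF blur or offset.

    Useful wherever a test wants the raw wrapped-exponential statistics.
    """
    return AcquisitionConfig(dead_time_s=0.0, irf_sigma_s=0.0, irf_center_s=0.0)
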