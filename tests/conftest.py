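import numpy as np
import pytest

import hydrospec as hs


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded study-scale dataset (80 samples x 264 points x 3 channels)."""
    spectra, labels = hs.simulate_dataset(hs.SimConfig(seed=1))
    return spectra, labels


@pytest.fixture(scope="session")
def quiet_config():
    """Generator configuration with every noise source switched off."""
    return hs.SimConfig(
        seed=0,
        moisture_sd=0.0,
        scan_noise_sd=0.0,
        leaf_offset_sd=0.0,
        leaf_tilt_sd=0.0,
        power_gain_sd=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
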