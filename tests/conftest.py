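import numpy as np
import pytest

from scaletomo import synthetic
from scaletomo.volumes import GreyVolume


@pytest.fixture(scope="session")
def noiseless_scale():
    """Small noiseless, ring-free synthetic scale (truth + rendering)."""
    cfg = synthetic.SyntheticScaleConfig(
        shape=(48, 64, 224), noise_sigma=0.0, ring_amplitude=0.0, seed=5
    )
    truth, grey = synthetic.simulate_scale(cfg)
    return cfg, truth, grey


@pytest.fixture(scope="session")
def noisy_scale():
    """Small synthetic scale with default noise and rings."""
    cfg = synthetic.SyntheticScaleConfig(shape=(48, 64, 224), seed=7)
    truth, grey = synthetic.simulate_scale(cfg)
    return cfg, truth, grey


@pytest.fixture(scope="session")
def embedded_scale():
    """Air-embedded float rendering for tilt-estimation tests."""
    cfg = synthetic.SyntheticScaleConfig(shape=(48, 80, 112), seed=3)
    _, grey = synthetic.simulate_scale(cfg)
    vol = synthetic.embed_in_air(
        GreyVolume(grey.data.astype(np.float64)), 16, air_value=cfg.grey_air
    )
    return cfg, vol
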