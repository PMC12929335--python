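import numpy as np
import pytest

from hepafat.attenuation import PhantomVolume


@pytest.fixture
def uniform_phantom():
    """Small phantom: liver block at 42.8 HU, spleen block at 34.2 HU, air elsewhere."""
    image = np.full((12, 12, 8), -1000.0)
    mask = np.zeros((12, 12, 8), dtype=int)
    image[2:6, 2:6, 2:6] = 42.8
    mask[2:6, 2:6, 2:6] = 1
    image[8:11, 8:11, 2:5] = 34.2
    mask[8:11, 8:11, 2:5] = 2
    return PhantomVolume(image=image, mask=mask, spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
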