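import numpy as np
import pytest

from mammoseg.io import ImageVolume, LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    return ImageVolume(data=rng.normal(100, 20, (16, 16, 16)), spacing=(1.0, 1.0, 1.5))


@pytest.fixture
def blob_mask():
    data = np.zeros((16, 16, 16), dtype=np.uint8)
    data[4:9, 5:10, 6:11] = 1
    return LabelMask(data=data, spacing=(1.0, 1.0, 1.5))
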