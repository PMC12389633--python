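import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Random 16x16 RGB uint8 image."""
    return rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)


@pytest.fixture
def voc_folder(tmp_path):
    """Small synthetic VOC dataset on disk."""
    from plantdet.synthetic_fixtures import make_dataset

    out = tmp_path / "voc"
    make_dataset(8, out, seed=3, size_pool=((160, 120), (128, 128)))
    return out
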