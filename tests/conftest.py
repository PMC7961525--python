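import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wce3dct.bayer import blocks_from_image
from wce3dct.synthetic import SceneParams, generate_wce
from wce3dct.transform import dct3d_fast_batch

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def corpus_images():
    """Three small synthetic scenes: (rgb, mosaic) pairs."""
    return [generate_wce(SceneParams(height=96, width=96, seed=s)) for s in range(3)]


@pytest.fixture(scope="session")
def corpus_blocks(corpus_images):
    """Level-shifted spatial blocks pooled over the corpus, (n, 4, 4, 4)."""
    return np.concatenate(
        [blocks_from_image(m).astype(np.float64) - 128.0 for _, m in corpus_images]
    )


@pytest.fixture(scope="session")
def corpus_spectra(corpus_blocks):
    return dct3d_fast_batch(corpus_blocks)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210305)
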