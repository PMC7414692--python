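import numpy as np
import pytest

from rpecount import AnnotatedImage, MosaicSpec, generate_mosaic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_mosaic():
    """A 96x96 mosaic with 30 cells; enough structure for feature tests."""
    return generate_mosaic(MosaicSpec(height=96, width=96, n_cells=30, seed=5))


@pytest.fixture
def textured_image(rng):
    """A small random grayscale image with a few annotations."""
    return AnnotatedImage(
        pixels=rng.random((48, 48)), annotations=[(10, 12), (30, 25), (40, 40)], id="tex"
    )


@pytest.fixture(scope="session")
def counting_benchmark():
    """The scaled-down end-to-end experiment, trained once per session.

    50 mosaics of 128x128 px with 40-60 cells and exposure gain in
    [0.4, 1.0], split 40 train / 10 test; MLP with hidden layers [200, 200]
    and the ridge baseline trained on identical features and labels.
    """
    from rpecount.benchmark import run_counting_benchmark

    return run_counting_benchmark(seed=1)
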