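import numpy as np
import pytest

from nmjkit import synthetic as syn
from nmjkit.stack import ImageStack


@pytest.fixture
def small_puncta():
    """A small noisy puncta phantom with its ground truth."""
    spec = syn.PunctaPhantomSpec(shape=(16, 96, 96), n_puncta=8, seed=7)
    return syn.gen_puncta_stack(spec)


@pytest.fixture
def flat_stack():
    return ImageStack(
        np.full((3, 32, 32), 10, dtype=np.uint8), spacing=(0.25, 0.1, 0.1)
    )


def random_stack(seed, shape=(3, 32, 32)):
    rng = np.random.default_rng(seed)
    return ImageStack(
        rng.integers(0, 256, size=shape, dtype=np.uint8).astype(np.uint8),
        spacing=(0.5, 0.1, 0.1),
    )
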