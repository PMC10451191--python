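import numpy as np
import pytest

from tailseg.data_io import LabeledImage
from tailseg.network import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_net_config():
    """Desk-scale network: one block per stage, width 4."""
    return NetworkConfig(base_width=4, stage_blocks=(1, 1, 1, 1))


def make_labeled(mask, identifier="item", image=None):
    mask = np.asarray(mask)
    if image is None:
        image = np.zeros(mask.shape)
    return LabeledImage(image, mask, identifier)


@pytest.fixture
def handmade_dataset():
    """Three small images with hand-countable class content (C=4)."""
    return [
        make_labeled([[0, 1], [1, 4]], "a"),
        make_labeled([[0, 0], [0, 0]], "b"),
        make_labeled([[2, 2], [3, 1]], "c"),
    ]
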