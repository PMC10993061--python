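import dataclasses

import numpy as np
import pytest

from fiberbrush import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantoms():
    """Six 64x64 phantoms (three per class) for degradation/IQ tests."""
    images = []
    for i in range(6):
        preset = phantom.PRESETS[
            "neoplastic" if i % 2 else "non_neoplastic"
        ]
        spec = dataclasses.replace(
            preset, height_px=64, width_px=64, seed=100 + i
        )
        images.append(phantom.generate_phantom(spec).image)
    return images
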