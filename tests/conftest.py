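"""Shared test fixtures.

Expensive synthetic images are generated once per session and reused.
"""

from __future__ import annotations

import numpy as np
import pytest

from mscpheno.fixtures import generate_image
from mscpheno.preprocess import preprocess_image


EASY_KWARGS = dict(
    n_single=4, clusters=[2], noise_sd=0.0, shape=(448, 448), gap=12
)


@pytest.fixture(scope="session")
def easy_fixture():
    """One noise-free, well-separated synthetic micrograph with truth."""
    img, truth, entry = generate_image(seed=1, **EASY_KWARGS)
    return img, truth, entry


@pytest.fixture(scope="session")
def noisy_fixture():
    """One realistic (noisy) synthetic micrograph with truth."""
    img, truth, entry = generate_image(
        n_single=5, clusters=[], noise_sd=0.01, seed=3, shape=(448, 448)
    )
    return img, truth, entry


@pytest.fixture(scope="session")
def preprocessed_noisy(noisy_fixture):
    img, truth, entry = noisy_fixture
    return preprocess_image(img)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
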