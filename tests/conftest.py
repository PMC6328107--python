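import numpy as np
import pytest

from ppoc import SampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blobs():
    """Two far-separated tight 2-D blobs of 30 points each, labels attached."""
    gen = np.random.default_rng(7)
    a = gen.normal([0.0, 0.0], 0.05, size=(30, 2))
    b = gen.normal([10.0, 10.0], 0.05, size=(30, 2))
    labels = np.repeat([0, 1], 30)
    return SampleSet(np.vstack([a, b]), labels=labels)


@pytest.fixture
def random_samples(rng):
    return SampleSet(rng.uniform(0, 1, size=(100, 3)))
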