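import numpy as np
import pytest

from wheezesep import HyperParams, SegmentSet, StftConfig, WeightScheme


@pytest.fixture
def config():
    return StftConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_segments(rng, f=5, lengths=(6, 4), labels=(0, 1)):
    return SegmentSet(
        segments=[rng.uniform(0.0, 2.0, (f, t)) for t in lengths],
        labels=list(labels)[: len(lengths)],
    )


@pytest.fixture
def small_segments(rng):
    return random_segments(rng)


@pytest.fixture
def small_hp():
    return HyperParams(k_r=3, k_w=2, max_iter=10, seed=7)


@pytest.fixture
def default_weights():
    return WeightScheme()
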