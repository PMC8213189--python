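import numpy as np
import pytest

from escorthist import ProbabilityHistogram


def make_hist(sparse: dict[int, float]) -> ProbabilityHistogram:
    """Histogram from a {bin: prob} mapping."""
    probs = np.zeros(256)
    for g, p in sparse.items():
        probs[g] = p
    return ProbabilityHistogram(probs=probs)


def random_histogram(rng: np.random.Generator, k: int = 256) -> ProbabilityHistogram:
    """Random histogram with mass on k uniformly chosen bins."""
    bins = rng.choice(256, size=k, replace=False)
    weights = rng.random(k) + 1e-3
    probs = np.zeros(256)
    probs[bins] = weights / weights.sum()
    return ProbabilityHistogram(probs=probs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
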