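import numpy as np
import pytest

from thresholdlogic.fixtures import worked_examples
from thresholdlogic.model import ThresholdFunction


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


def random_threshold_function(rng: np.random.Generator, n: int) -> ThresholdFunction:
    """Random sparse neuron for round-trip and property tests."""
    subsets = [
        tuple(i + 1 for i in range(n) if mask >> i & 1) for mask in range(1, 2**n)
    ]
    k = int(rng.integers(0, min(len(subsets), 8) + 1))
    chosen = rng.choice(len(subsets), size=k, replace=False) if k else []
    terms = {}
    for idx in chosen:
        weight = int(rng.integers(-4, 5))
        if weight:
            terms[subsets[int(idx)]] = weight
    return ThresholdFunction(n, terms)
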