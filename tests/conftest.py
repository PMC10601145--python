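import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, n, p_gc=0.5):
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


@pytest.fixture
def make_seq():
    return random_sequence
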