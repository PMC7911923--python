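import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20210250)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))
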