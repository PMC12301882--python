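import numpy as np
import pytest

from cas12mux import synthetic_manifest


@pytest.fixture(scope="session")
def sites():
    """The deterministic six-gene synthetic reference set."""
    return synthetic_manifest()


@pytest.fixture(scope="session")
def site(sites):
    """A single plus-strand target site."""
    return sites[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
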