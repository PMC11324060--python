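import pytest

from pnpkit import synthetic


@pytest.fixture(scope="session")
def toy_catalog():
    return synthetic.make_toy_catalog()


@pytest.fixture(scope="session")
def composites(toy_catalog):
    """All realizable clean two-fragment constructs from the toy catalog."""
    return synthetic.enumerate_composites(toy_catalog)


@pytest.fixture(scope="session")
def small_library():
    """200-record synthetic library with NP reference and true statuses."""
    return synthetic.make_synthetic_library(200, np_fraction=0.2, seed=7)
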