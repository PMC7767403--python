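import pytest

from snpbindshift import (
    build_duplex,
    build_toy_complex,
    mutate_pair,
    place_bridging_water,
)
from snpbindshift.synthetic_data import DEFAULT_SEQUENCE, DEFAULT_SITE


@pytest.fixture(scope="session")
def wt_duplex():
    return build_duplex(DEFAULT_SEQUENCE)


@pytest.fixture(scope="session")
def mut_duplex(wt_duplex):
    return mutate_pair(wt_duplex, DEFAULT_SITE, "CG")


@pytest.fixture(scope="session")
def site():
    return DEFAULT_SITE


@pytest.fixture(scope="session")
def wet_complex(mut_duplex, site):
    """Mutant toy complex with its bridging water in place."""
    return place_bridging_water(build_toy_complex(mut_duplex, site), site)
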