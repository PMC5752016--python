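import numpy as np
import pytest

from crmscan.simulate import standard_fixtures

#: One deterministic fixture bundle shared by the whole suite.
FIXTURE_SEED = 1234


@pytest.fixture(scope="session")
def fixtures():
    return standard_fixtures(FIXTURE_SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(999)


@pytest.fixture(scope="session")
def tiny_promoters():
    """A handmade 4-promoter set small enough to check by eye."""
    from crmscan.promoters import PromoterSet

    return PromoterSet(
        {
            "g1": "TTAAAATAAT",
            "g2": "ACGTACGTAC",
            "g3": "GGGGGGGGGG",
            "g4": "ATATATATAT",
        },
        region_length=10,
    )
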