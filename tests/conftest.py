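import pytest

from aqpkit.io_formats import load_sdp_table
from aqpkit.synthetic_data import (
    CANONICAL_GROUPS,
    FamilySpec,
    build_reference_set,
    simulate_family,
)


@pytest.fixture(scope="session")
def sdp_table():
    return load_sdp_table()


@pytest.fixture(scope="session")
def references():
    return build_reference_set()


@pytest.fixture(scope="session")
def references_by_key(references):
    return {(r.subfamily, r.group): r for r in references}


def _family(divergence, seed, n=50):
    counts = {(s, CANONICAL_GROUPS[s]): n for s in CANONICAL_GROUPS}
    return simulate_family(FamilySpec(counts=counts, divergence=divergence, seed=seed))


@pytest.fixture(scope="session")
def family_low_divergence():
    """50 records per subfamily at 15% divergence, fixed seed."""
    return _family(0.15, seed=42)


@pytest.fixture(scope="session")
def family_high_divergence():
    """50 records per subfamily at 25% divergence, fixed seed."""
    return _family(0.25, seed=43)
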