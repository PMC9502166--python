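import pytest

from efam_forge.synth_fixtures import (
    FixtureConfig,
    generate_families,
    generate_hits,
)


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted-family fixture shared across tests."""
    config = FixtureConfig(seed=42, n_families=8, family_size_range=(3, 6))
    proteins, truth = generate_families(config)
    allvall, ref_hits = generate_hits(proteins, truth, config)
    return config, proteins, truth, allvall, ref_hits
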