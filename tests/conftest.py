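import pytest

from maldigel import simulate_protein_db
from maldigel.digestion import digest_database


@pytest.fixture(scope="session")
def small_db():
    """50 random proteins, the standing database for search tests."""
    return simulate_protein_db(50, length_range=(100, 400), seed=20240)


@pytest.fixture(scope="session")
def small_index(small_db):
    return digest_database(small_db)
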