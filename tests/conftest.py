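import numpy as np
import pytest

from tmejsig import RefGenome, fixture_dataset, normalize_deletion


@pytest.fixture(scope="session")
def fixture_sim():
    """Small deterministic MA-line dataset shared across tests."""
    return fixture_dataset(seed=42)


@pytest.fixture(scope="session")
def fixture_ref(fixture_sim):
    return RefGenome(fixture_sim.reference)


@pytest.fixture(scope="session")
def fixture_deletions(fixture_sim, fixture_ref):
    """Normalized deletion events (>= 1 deleted base, non-SNV) of the fixture set."""
    return [
        normalize_deletion(fixture_ref, r)
        for r in fixture_sim.records
        if r.deletion_size >= 1 and not r.is_snv
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
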