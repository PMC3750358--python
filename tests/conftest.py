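import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bulkbarcode as bb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_db():
    """Small two-gene synthetic reference library (8 species x 3 specimens)."""
    return bb.simulate_reference_db(n_species=8, n_per_species=3, seed=101)


@pytest.fixture(scope="session")
def coi_seqs(sim_db):
    return {r.specimen_id: r.sequence for r in sim_db.by_gene("COI")}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
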