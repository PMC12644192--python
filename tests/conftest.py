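import pytest

from claimscohort.claims import default_code_lists
from claimscohort.simulate import SimulationParameters, generate_claims_database


@pytest.fixture(scope="session")
def codes():
    return default_code_lists()


@pytest.fixture(scope="session")
def small_noisy_db():
    """A 400-patient database with imperfect emission and background noise."""
    db, gt = generate_claims_database(SimulationParameters.noisy(n_patients=400, seed=11))
    return db, gt


@pytest.fixture(scope="session")
def small_perfect_db():
    """A 400-patient database with perfect phenotype emission, no noise."""
    db, gt = generate_claims_database(SimulationParameters(n_patients=400, seed=5))
    return db, gt
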