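import pytest

from mitolineage import datasets


@pytest.fixture(scope="session")
def fisher():
    """Deterministic survey-shaped fixture: (alignment, partitions, samples)."""
    return datasets.fisher_fixture()


@pytest.fixture(scope="session")
def study_sim():
    """One survey-shaped stochastic replicate with its truth record."""
    return datasets.simulate_study(1)
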