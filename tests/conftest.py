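import pytest

from sodasim import calibrate, generate_cohort, load_parameters


@pytest.fixture(scope="session")
def defaults():
    """Packaged default parameter set and run configuration."""
    return load_parameters()


@pytest.fixture(scope="session")
def pset(defaults):
    return defaults[0]


@pytest.fixture(scope="session")
def config(defaults):
    return defaults[1]


@pytest.fixture(scope="session")
def pop_spec():
    """Population spec calibrated to the survey weight moments."""
    return calibrate(seed=1959)


@pytest.fixture(scope="session")
def cohort_20k(pop_spec):
    return generate_cohort(pop_spec.with_n(20_000), seed=42)
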