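import numpy as np
import pytest

from polarpva.rates import Rate, VitalRates, uniform_survival
from polarpva.lifecycle import stable_age_distribution
from polarpva.synthetic import SyntheticSpec, generate_vital_rates


@pytest.fixture(scope="session")
def toy_rates():
    """Small growing population with no rate uncertainty."""
    return VitalRates(
        "TOY",
        uniform_survival(0.93, 0.0, by_class={"coy": 0.65}),
        litter_production={a: Rate(0.9, 0.0) for a in range(5, 31)},
        litter_size=Rate(1.7, 0.0),
    )


@pytest.fixture(scope="session")
def uncertain_rates():
    """Same life cycle with survey-scale standard errors attached."""
    return VitalRates(
        "UNC",
        uniform_survival(0.93, 0.03, by_class={"coy": 0.65}),
        litter_production={a: Rate(0.9, 0.05) for a in range(5, 31)},
        litter_size=Rate(1.7, 0.08),
    )


@pytest.fixture(scope="session")
def toy_sad(toy_rates):
    return stable_age_distribution(toy_rates)


@pytest.fixture(scope="session")
def uncertain_sad(uncertain_rates):
    return stable_age_distribution(uncertain_rates)


@pytest.fixture(scope="session")
def calibrated_rates():
    """Synthetic table calibrated to deterministic growth 1.03/yr."""
    return generate_vital_rates(SyntheticSpec(target_lambda=1.03))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
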