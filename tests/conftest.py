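import numpy as np
import pytest

from duckgrowth import AgeWeightSeries, SyntheticSpec, fixture, generate


@pytest.fixture(scope="session")
def kuzi():
    return fixture("kuzi")


@pytest.fixture(scope="session")
def polish_pekin():
    return fixture("polish_pekin")


@pytest.fixture(scope="session")
def peking():
    return fixture("peking")


@pytest.fixture(scope="session")
def all_breeds(kuzi, polish_pekin, peking):
    return {"kuzi": kuzi, "polish_pekin": polish_pekin, "peking": peking}


@pytest.fixture
def noise_free_series():
    """Factory: exact series from a model's curve on a breed grid."""

    def make(model, params, ages, seed=0):
        return generate(SyntheticSpec(model, params, ages, noise_sd=0.0, seed=seed))[0]

    return make


@pytest.fixture
def flat_series():
    return AgeWeightSeries("flat", np.arange(1.0, 9.0), np.full(8, 500.0))
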