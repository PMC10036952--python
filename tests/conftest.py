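import numpy as np
import pytest

from percmem import (
    DisambiguationSchedule,
    MCMCConfig,
    ObserverParams,
    build_triplets,
    simulate_session,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def onset_schedule():
    return DisambiguationSchedule.from_variant("onset_only")


@pytest.fixture(scope="session")
def default_params():
    return ObserverParams()


@pytest.fixture(scope="session")
def small_session(onset_schedule, default_params):
    """A deterministic 400-prime session with occasional misses."""
    return simulate_session(
        default_params, onset_schedule, 400, np.random.default_rng(7), "obs01"
    )


@pytest.fixture(scope="session")
def small_triplets(small_session):
    return build_triplets(small_session)


@pytest.fixture(scope="session")
def quick_mcmc():
    """Short sampler settings for operation-level tests.

    Too short for the 1.01 split-R-hat threshold; tests using it suppress
    ConvergenceWarning and only assert posterior-location properties.
    """
    return MCMCConfig(n_warmup=3000, n_steps=6000, thin=12, seed=99)
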