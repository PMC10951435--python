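import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aneudyn as ad

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def map_params():
    """Joint posterior-mode parameters of the heat-stress experiment."""
    return ad.map_params()


@pytest.fixture(scope="session")
def reduced_params():
    """Small-population, time-compressed analogue of the inferred dynamics.

    Same qualitative structure as the experiment (aneuploid wave fixes
    early, the euploid mutant takes over much later from a small relative
    fitness edge), but with N=10^4 and ~4x faster selective timescale so a
    full sweep completes within ~900 generations.
    """
    return ad.ModelParams(
        mu=1e-5, delta=1e-2, w=(1.0, 1.091, 1.104, 1.117),
        N=10_000, horizon=900,
    )


@pytest.fixture(scope="session")
def reduced_prior():
    """Prior matched to the reduced-scale regime for recovery tests."""
    return ad.PriorSpec(
        mu_bounds=(1e-7, 1e-3),
        delta_bounds=(1e-4, 5e-2),
        fitness_mean=(1.09, 1.10, 1.12),
        fitness_cov=tuple(tuple(r) for r in (np.eye(3) * 4e-4)),
    )


@pytest.fixture(scope="session")
def reduced_observations(reduced_params):
    """A non-degenerate synthetic observation record at reduced scale."""
    exp = ad.generate_observations(reduced_params, seed=1, horizon=900)
    assert not exp.degenerate
    return exp.observations
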