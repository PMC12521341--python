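import numpy as np
import pytest
from hypothesis import settings

import celldose as cd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def two_pop_model():
    return cd.build_two_population(cd.TwoPopulationParams(alpha=0.5, beta=0.5))


@pytest.fixture(scope="session")
def two_pop_problem(two_pop_model):
    return cd.default_problem(two_pop_model, "two_population")


@pytest.fixture(scope="session")
def two_pop_solution(two_pop_problem):
    """The reference two-population optimum, solved once per session."""
    return cd.solve(two_pop_problem)


@pytest.fixture(scope="session")
def nb_reduced_model():
    return cd.reduce_neuroblastoma(
        cd.NeuroblastomaReducedParams(lam=0.2, delta=0.1, delta_apop=0.3)
    )


@pytest.fixture(scope="session")
def nb_problem(nb_reduced_model):
    return cd.default_problem(nb_reduced_model, "neuroblastoma")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
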