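import numpy as np
import pytest

from telehealth_cea import fixtures
from telehealth_cea.markov import MarkovParameters, build_transition_matrix


def microsimulate(params: MarkovParameters, start_state: str, n_walkers: int,
                  seed: int) -> np.ndarray:
    """Individual-level Monte Carlo oracle for the cohort trace.

    Simulates ``n_walkers`` independent walkers through the transition
    matrix and returns empirical state-occupancy fractions with the same
    shape as a cohort trace. Independent of the cohort engine's matrix
    propagation (it uses per-walker categorical draws).
    """
    rng = np.random.default_rng(seed)
    mat = build_transition_matrix(params)
    cum = np.cumsum(mat, axis=1)
    states = np.full(n_walkers, {"in_person": 0, "telehealth": 1}[start_state])
    occ = np.zeros((params.horizon + 1, 3))
    for t in range(params.horizon + 1):
        occ[t] = np.bincount(states, minlength=3) / n_walkers
        if t == params.horizon:
            break
        u = rng.random(n_walkers)
        states = (u[:, None] > cum[states]).sum(axis=1)
    return occ


@pytest.fixture(scope="session")
def microsim():
    return microsimulate


@pytest.fixture(scope="session")
def model_a():
    return fixtures.MODEL_A


@pytest.fixture(scope="session")
def urban_profile():
    return fixtures.URBAN_PROFILE
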