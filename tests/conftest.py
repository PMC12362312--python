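import numpy as np
import pytest

from rfdti.dina_core import (
    AttributeProfileSet,
    ItemParams,
    QMatrix,
    ResponseMatrix,
    ideal_responses,
    response_probabilities,
    simulate_item_params,
    simulate_profiles,
    simulate_responses,
)
from rfdti.missingness import apply_mcar, select_subsample


@pytest.fixture(scope="session")
def identifiable_q() -> QMatrix:
    """J=9, K=3 Q matrix embedding an identity submatrix twice (identifiable)."""
    eye = np.eye(3, dtype=int)
    mixed = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
    return QMatrix(np.vstack([eye, eye, mixed]))


@pytest.fixture(scope="session")
def small_complete(identifiable_q):
    """Small complete DINA dataset with known truth."""
    profiles = simulate_profiles(150, 3, rho=0.5, seed=11)
    params = simulate_item_params(identifiable_q.n_items, seed=12)
    data = simulate_responses(profiles, identifiable_q, params, seed=13)
    return data, identifiable_q, profiles, params


@pytest.fixture(scope="session")
def small_missing(small_complete):
    """The small dataset with 20% MCAR missingness on an 80% subsample."""
    data, q, profiles, params = small_complete
    sub = select_subsample(data.n_examinees, 0.8, seed=14)
    missing = apply_mcar(data, 0.2, sub, seed=15)
    return missing, q, profiles, params


@pytest.fixture(scope="session")
def ideal_dataset(identifiable_q):
    """Noiseless data: responses equal the conjunctive ideal responses."""
    profiles = simulate_profiles(200, 3, rho=0.5, seed=21)
    values = ideal_responses(profiles.profiles, identifiable_q.entries).astype(float)
    return ResponseMatrix(values), identifiable_q, profiles


@pytest.fixture(scope="session")
def wide_complete():
    """A 30-item dataset matching the generating design (for imputation tests)."""
    from rfdti.dina_core import generate_q_matrix

    q = generate_q_matrix(30, 3, seed=31)
    profiles = simulate_profiles(200, 3, rho=0.5, seed=32)
    params = simulate_item_params(30, seed=33)
    data = simulate_responses(profiles, q, params, seed=34)
    p_true = response_probabilities(profiles.profiles, q, params)
    return data, q, profiles, params, p_true
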