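import numpy as np
import pytest

from dcmfill.cohort import (DEFAULT_TRUE_MODEL_ID, model_family,
                            simulate_cohort)
from dcmfill.forward import EffectiveConnectivity, HemodynamicParams


@pytest.fixture(scope="session")
def family():
    return model_family()


@pytest.fixture(scope="session")
def true_model(family):
    return family[DEFAULT_TRUE_MODEL_ID - 1]


@pytest.fixture(scope="session")
def small_cohort(true_model):
    """Four full-length subjects from the true model (shared, read-only)."""
    return simulate_cohort(true_model, 4, seed=101)


@pytest.fixture
def simple_conn():
    """Chain V -> M driven by one input, with prior-mean hemodynamics."""
    A = -np.eye(4)
    A[2, 0] = 0.4
    B = np.zeros((2, 4, 4))
    C = np.zeros((4, 2))
    C[0, 0] = 4.6
    C[1, 1] = 4.6
    return EffectiveConnectivity(A, B, C)


@pytest.fixture
def prior_hemo():
    return [HemodynamicParams.prior_means() for _ in range(4)]


def box_stimulus(n_steps, dt, m=2, period=10.0, duty=0.5):
    t = np.arange(n_steps) * dt
    u = np.zeros((n_steps, m))
    u[:, 0] = (t % period < period * duty).astype(float)
    if m > 1:
        u[:, 1] = (t % (period * 1.25) < period * 0.25).astype(float)
    return u
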