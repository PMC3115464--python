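import numpy as np
import pandas as pd
import pytest

from costtraj import TrajectoryProfile, load_definitions
from costtraj.simulate import SimulationConfig, preset_params, simulate_population


@pytest.fixture(scope="session")
def definitions():
    return load_definitions()


@pytest.fixture(scope="session")
def achd_params():
    """Published total-population quadruple for acute coronary heart disease."""
    return preset_params("achd")


@pytest.fixture(scope="session")
def achd_profile(achd_params):
    """Noiseless 41-point profile from the ACHD quadruple, nominal unit SEs."""
    return TrajectoryProfile.from_params(achd_params, disease="achd")


@pytest.fixture(scope="session")
def small_population():
    """A 300-person simulated population shared across detection/cohort tests."""
    cfg = SimulationConfig(n_persons=300, seed=1)
    persons, claims, truth = simulate_population(cfg, seed=1)
    return cfg, persons, claims, truth


def make_noisy_profile(params, sigma, rng, window=20):
    """Profile-level replicate: model means plus N(0, sigma) at each month."""
    from costtraj.model import evaluate_cost

    m = np.arange(-window, window + 1)
    mean = evaluate_cost(m, params) + rng.normal(0.0, sigma, len(m))
    return TrajectoryProfile(
        m=m,
        mean=mean,
        se=np.full(len(m), float(sigma)),
        n_at_risk=np.full(len(m), 500),
    )
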