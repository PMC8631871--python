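import numpy as np
import pytest

from phenoforecast import synthgen as sg


@pytest.fixture(scope="session")
def linear_records():
    """Noiseless linear-growth cohort (exact-recovery substrate)."""
    return sg.simulate_growth_curves(sg.linear_config(n_plants=3, seed=11))


@pytest.fixture(scope="session")
def logistic_records():
    """Default noisy logistic cohort at reduced plant count."""
    cfg = sg.GrowthSimConfig(n_plants=8, seed=5)
    return sg.simulate_growth_curves(cfg)


@pytest.fixture(scope="session")
def saturating_records():
    """Noiseless logistic plants whose plateau is reached inside the
    training windows (tree learners cannot extrapolate past it)."""
    cfg = sg.GrowthSimConfig(
        n_plants=6,
        noise_sd=0.0,
        midpoint=sg.DistSpec(13.5, 0.5, low=12.0, high=15.0),
        rate=sg.DistSpec(1.3, 0.1, low=1.0),
        seed=2,
    )
    return sg.simulate_growth_curves(cfg)


def random_mask(rng: np.random.Generator, shape=(16, 16), p=0.4) -> np.ndarray:
    return rng.random(shape) < p


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
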