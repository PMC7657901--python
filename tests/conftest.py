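import numpy as np
import pytest

from milbridge.sde_models import DiffusionModel, gbm_exact_sample, gbm_model


@pytest.fixture(scope="session")
def gbm():
    return gbm_model()


@pytest.fixture(scope="session")
def theta():
    return (1.0, 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture(scope="session")
def obs_path(theta):
    """One GBM path with the study design: x0=100, 20 observations, dt=0.05."""
    rng = np.random.default_rng(7)
    times = np.linspace(0.0, 1.0, 21)
    values = [100.0]
    for _ in range(20):
        values.append(gbm_exact_sample(values[-1], 0.05, theta, rng))
    return times, np.array(values)


@pytest.fixture(scope="session")
def flat_sigma_model():
    """A diffusion with state-independent sigma (sigma' = 0), for the
    Milstein -> Euler reduction checks: dX = theta0 X dt + theta1 dB."""

    def drift(y, th):
        return float(th[0]) * np.asarray(y, dtype=float)

    def diffusion(y, th):
        return float(th[1]) * np.ones_like(np.asarray(y, dtype=float))

    def diffusion_dy(y, th):
        return np.zeros_like(np.asarray(y, dtype=float))

    return DiffusionModel(
        name="flat",
        drift=drift,
        diffusion=diffusion,
        diffusion_dy=diffusion_dy,
        state_lower=-np.inf,
        positive_params=(False, True),
    )
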