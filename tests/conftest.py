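import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ivgp import (
    NoiseModel,
    PhysicsConfig,
    default_trial_config,
    simulate_study,
    simulate_trial,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def physics():
    return PhysicsConfig()


@pytest.fixture(scope="session")
def noise_free_trial_rfa():
    """One RF_A (exponential-curve) trial with all noise off."""
    return simulate_trial(default_trial_config("RF_A", trial_id="A01", noise=NoiseModel.none()))


@pytest.fixture(scope="session")
def noise_free_trial_rft():
    """One RF_T (sigmoid-curve) trial with all noise off."""
    return simulate_trial(default_trial_config("RF_T", trial_id="T01", noise=NoiseModel.none()))


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 2+3-trial noisy study dataset on disk, with its ground truth."""
    root = tmp_path_factory.mktemp("study")
    truth = simulate_study(root, seed=7, n_rft=2, n_rfa=3)
    return root, truth


def grid_curve(values, bottle_id="b", step_min=10.0):
    """GasCurve on a regular grid from plain values (test helper)."""
    from ivgp import GasCurve

    values = np.asarray(values, dtype=float)
    return GasCurve(
        bottle_id=bottle_id,
        trial_id="t",
        grid_min=np.arange(values.size) * step_min,
        ml_stp_per_g_dm=values,
    )


@pytest.fixture
def make_curve():
    return grid_curve
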