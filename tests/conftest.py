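import numpy as np
import pytest

from fcsbind import (ObservationVolume, BindingDiffusionParams, GroundTruth,
                     SimulationConfig, simulate_binding_trace)


@pytest.fixture(scope="session")
def volume():
    return ObservationVolume(w0=0.22, z0=0.6)


@pytest.fixture(scope="session")
def water_params():
    return BindingDiffusionParams(N=48.0, D=3.5, kon_star=1.725, koff=35.0)


@pytest.fixture(scope="session")
def small_truth(volume):
    """A low-occupancy ground truth that keeps simulations cheap."""
    return GroundTruth(BindingDiffusionParams(N=5.0, D=3.5, kon_star=0.0, koff=35.0),
                       volume, "small-diffusion")


@pytest.fixture(scope="session")
def small_diffusion_trace(small_truth):
    cfg = SimulationConfig(duration=10.0, dt=2e-4, seed=7)
    return simulate_binding_trace(cfg, small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
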