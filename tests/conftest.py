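import numpy as np
import pytest

import fishquant as fq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale acquisition: short stacks, one small field, two nuclei."""
    return fq.SimulationParams(
        field_px=64,
        n_frames_signal=400,
        n_frames_dapi=100,
        n_nuclei=2,
        nucleus_radius_px=(8.0, 10.0),
        p_on=0.02,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_field(small_params):
    """One simulated field shared by read-only tests."""
    return fq.simulate_field(small_params)


@pytest.fixture(scope="session")
def threshold_model():
    """The frame-threshold regression calibrated once per session."""
    return fq.calibrate_threshold_model(n_images=20, seed=7)
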