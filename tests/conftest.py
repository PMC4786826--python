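import numpy as np
import pytest

import spineshm as sh


@pytest.fixture(scope="session")
def default_cfg() -> sh.ExcitationConfig:
    return sh.ExcitationConfig(seed=7)


@pytest.fixture(scope="session")
def small_cfg() -> sh.ExcitationConfig:
    """Short pulse train for fast tests: 4 x 0.2 s pulses (5 Hz grid)."""
    return sh.ExcitationConfig(n_pulses=4, pulse_duration=0.2, seed=11)


@pytest.fixture(scope="session")
def default_model() -> sh.SpineModel:
    return sh.build_spine_model()


@pytest.fixture(scope="session")
def noiseless_model() -> sh.SpineModel:
    return sh.build_spine_model(noise_rms=0.0)


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_model, small_cfg) -> sh.PulseTrainRecording:
    force = sh.generate_excitation(small_cfg)
    return sh.simulate_recording(noiseless_model, force, small_cfg, noise_seed=1)


@pytest.fixture(scope="session")
def noisy_recording(default_model, small_cfg) -> sh.PulseTrainRecording:
    force = sh.generate_excitation(small_cfg)
    return sh.simulate_recording(default_model, force, small_cfg, noise_seed=1)


def single_mass_model(f0_hz: float = 350.0, mass: float = 0.1, zeta: float = 0.02,
                      noise_rms: float = 0.0) -> sh.SpineModel:
    """One grounded mass whose undamped resonance is f0_hz; drive and sensor
    coincide."""
    k = mass * (2 * np.pi * f0_hz) ** 2
    c = 2 * zeta * np.sqrt(k * mass)
    return sh.SpineModel(
        node_labels=("L1",), masses=(mass,), stiffnesses=(), dampings=(),
        ground_stiffness=k, ground_damping=c,
        sensor_attenuation=(1.0,), noise_rms=noise_rms,
    )
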