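import numpy as np
import pytest

from fpvs import OddballDesign, NoiseSpec, SignalSpec, SimConfig, simulate_recording
from fpvs.montage import channel_labels


@pytest.fixture(scope="session")
def design():
    return OddballDesign()


@pytest.fixture(scope="session")
def labels64():
    return list(channel_labels())


@pytest.fixture(scope="session")
def quiet_recording(design):
    """Zero-noise recording with a single 2 Hz oddball cosine (A=0.2),
    uniform topography, 4 channels — the closed-form recovery fixture."""
    cfg = SimConfig(n_channels=4, sampling_rate=1024.0, n_trials_per_condition=2, seed=3)
    sig = SignalSpec(
        base_harmonic_amplitudes=[],
        oddball_harmonic_amplitudes=[(1, 0.2)],
        base_topography=np.ones(4),
        oddball_topography=np.ones(4),
    )
    silent = NoiseSpec(noise_scale=0.0, alpha_amplitude=0.0)
    return simulate_recording(design, sig, silent, cfg)
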