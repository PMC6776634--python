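import numpy as np
import pytest

from retinamech import synth


@pytest.fixture(scope="session")
def retina_tissue():
    """Soft-tissue SLS preset: K' = 0.7 kPa at 0.1 Hz, 1.7 kPa at 10 Hz."""
    return synth.TissueModel.retina_like()


@pytest.fixture(scope="session")
def sweep_protocol():
    return synth.IndentationProtocol.map_sweep(depth_um=15.0)


@pytest.fixture(scope="session")
def clean_trace(retina_tissue, sweep_protocol):
    return synth.simulate_indentation_trace(
        sweep_protocol, retina_tissue, probe_radius_um=57.0, noise_sd_um=0.0, seed=1
    )


def make_oscillation(
    f_hz: float,
    n_periods: int = 10,
    fs_hz: float = 500.0,
    h0: float = 0.3,
    f0: float = 0.12,
    phase: float = 0.0,
    mean_depth: float = 15.0,
    mean_load: float = 0.4,
):
    """Noise-free sinusoidal depth/load pair with a known phase lag."""
    n = int(round(n_periods / f_hz * fs_hz))
    t = np.arange(n) / fs_hz
    w = 2 * np.pi * f_hz
    depth = mean_depth + h0 * np.sin(w * t)
    load = mean_load + f0 * np.sin(w * t + phase)
    return t, depth, load
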