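import numpy as np
import pytest

from spnpipe import SimParams, analyze_session, simulate_session


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale baseline session (327 neurons, 300 s, seed 1)."""
    return simulate_session(SimParams(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_bundle):
    return analyze_session(default_bundle)


@pytest.fixture(scope="session")
def small_params():
    """A light session for tests that only need structure, not statistics."""
    return SimParams(n_neurons=60, session_length=120.0, bout_rate=4.0, seed=3)


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return simulate_session(small_params)


def fuzz_velocity(rng, n_frames=3000, frame_rate=30.0):
    """Random smooth velocity trace crossing both segmentation thresholds."""
    from scipy.ndimage import gaussian_filter1d

    scale = rng.uniform(0.1, 5.0)
    v = gaussian_filter1d(rng.normal(0.0, 1.0, n_frames), rng.uniform(5, 40))
    sd = v.std()
    if sd > 0:
        v *= scale / sd
    return v


def fuzz_dff(rng, n_frames=600, frame_rate=30.0, n_events=None):
    """Random smoothed ΔF/F-like trace with kernel-shaped events."""
    from spnpipe import smooth
    from spnpipe.simulate import gcamp_kernel

    noise = rng.normal(0.0, 0.05, n_frames)
    kernel = gcamp_kernel(frame_rate)
    x = noise.copy()
    if n_events is None:
        n_events = rng.integers(0, 8)
    for _ in range(n_events):
        i = rng.integers(0, n_frames - kernel.size)
        amp = rng.uniform(0.1, 1.5)
        x[i:i + kernel.size] += amp * kernel
    return smooth(x, 0.150, frame_rate)
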