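import numpy as np
import pytest

from impa.spectral_forward import (InterferogramStack, OpticalCavity,
                                   ProbeConfig, SpectrometerSpec,
                                   simulate_frame)


@pytest.fixture(scope="session")
def spec():
    return SpectrometerSpec()


@pytest.fixture(scope="session")
def probe():
    return ProbeConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stack(lengths, spec, refractive_index=1.0, visibility=0.4,
               sampling_rate=1000.0, noise_sd=0.0, seed=0,
               extra_cavities=()):
    """Stack of frames for one cavity following a length trajectory (m)."""
    lengths = np.asarray(lengths, float)
    rng = np.random.default_rng(seed)
    frames = np.stack([
        simulate_frame([OpticalCavity("c", d, refractive_index, visibility),
                        *extra_cavities],
                       spec, noise_sd=noise_sd, rng=rng)
        for d in lengths])
    time = np.arange(len(lengths)) / sampling_rate
    return InterferogramStack(time=time, frames=frames, spec=spec)


@pytest.fixture(scope="session")
def stack_factory():
    return make_stack
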