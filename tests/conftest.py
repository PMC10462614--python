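import numpy as np
import pytest

from spikenc.frontend import SpikeWave, build_dog_bank
from spikenc.scnn import IFConvLayer


@pytest.fixture(scope="session")
def digit_bank():
    """Two-channel DoG bank (fast: 2 channels, 7x7 window, pad 3)."""
    return build_dog_bank("digit")


@pytest.fixture(scope="session")
def character_bank():
    return build_dog_bank("character_natural")


@pytest.fixture()
def small_layer():
    """A small IF layer for fast simulation tests: 4 kernels, 2 inputs, 3x3."""
    return IFConvLayer.initialize(
        n_out=4, n_in=2, kernel_size=3, pad=1, seed=42, v_th=3.0
    )


def random_spike_wave(rng, T=10, C=2, H=8, W=8, p=0.15) -> SpikeWave:
    """A random spike wave obeying the at-most-one-spike-per-site invariant."""
    fires = rng.random((C, H, W)) < p
    times = rng.integers(0, T, size=(C, H, W))
    spikes = np.zeros((T, C, H, W), dtype=bool)
    c, h, w = np.nonzero(fires)
    spikes[times[c, h, w], c, h, w] = True
    return SpikeWave(spikes)


@pytest.fixture()
def spike_wave_factory():
    return random_spike_wave
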