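import numpy as np
import pytest

from frpsonet.synth import SynthConfig, make_channel_layout, synth_dataset


def rand_spd(rng: np.random.Generator, d: int, jitter: float = 0.5) -> np.ndarray:
    """Random well-conditioned SPD matrix."""
    A = rng.standard_normal((d, d))
    return A @ A.T + jitter * np.eye(d)


@pytest.fixture(scope="session")
def layout():
    return make_channel_layout()


@pytest.fixture(scope="session")
def high_snr_dataset():
    """Small, strongly separable trial set (low noise, strong P300)."""
    cfg = SynthConfig(seed=42, noise_sd=2.0, p300_amplitude=5.0)
    return synth_dataset(cfg, 160)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Very small default-condition trial set for protocol plumbing tests."""
    return synth_dataset(SynthConfig(seed=7), 100)
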