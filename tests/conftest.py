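import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def crandn(rng, shape):
    """Complex array with standard-normal real and imaginary parts."""
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


@pytest.fixture
def small_shift_dataset():
    """Noiseless shift-invariant dataset (no spatial variability)."""
    from shiftcpd.simulate import SimConfig, generate_dataset

    cfg = SimConfig(
        n_subjects=6,
        n_components=2,
        grid=(22, 22),
        n_voxels=300,
        n_timepoints=64,
        snr_db=np.inf,
        translation=0.0,
        rotation=0.0,
        spread=0.0,
        max_delay=4,
        seed=42,
    )
    return generate_dataset(cfg)
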