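import numpy as np
import pytest

from octapipe.synthetic_data import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free vessel-network phantom with ground truth."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=42))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom (speckle noise on)."""
    return generate_phantom(PhantomSpec(seed=42))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
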