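import numpy as np
import pytest

from artexus.config import ARConfig, PipelineConfig, SegmentConfig, WaveletConfig
from artexus.synthdata import TextureParams, gen_phantom


@pytest.fixture(scope="session")
def wavelet_cfg() -> WaveletConfig:
    return WaveletConfig()


@pytest.fixture(scope="session")
def small_ar_cfg() -> ARConfig:
    """Reduced model orders for fast unit tests on short signals."""
    return ARConfig(orders={"LF": 20, "MF": 12, "HF": 8, "TB": 16})


@pytest.fixture(scope="session")
def small_cfg(small_ar_cfg) -> PipelineConfig:
    return PipelineConfig(ar=small_ar_cfg)


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_phantom():
    """120x120 two-texture phantom (6x6 patch grid) for fast pipeline tests."""
    return gen_phantom(
        shape=(120, 120),
        inside=TextureParams(band=(0.03, 0.12)),
        outside=TextureParams(band=(0.18, 0.45)),
        seed=11,
    )


def random_stable_ar(rng: np.random.Generator, order: int) -> np.ndarray:
    """Random stable AR coefficients via uniform reflection coefficients."""
    k = rng.uniform(-0.95, 0.95, size=order)
    a = np.zeros(0)
    for i in range(order):  # Levinson step-up recursion
        a = np.concatenate([a + k[i] * a[::-1], [k[i]]])
    return a
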