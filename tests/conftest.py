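import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_wavelet():
    """Coarse scale grid for tests that do not probe scale resolution."""
    from autoregwtc.wavelet import WaveletParams

    return WaveletParams(dj=1.0 / 6.0)


@pytest.fixture(scope="session")
def default_periods():
    from autoregwtc.wavelet import WaveletParams

    return WaveletParams().periods(1.0)
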