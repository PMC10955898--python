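import numpy as np
import pytest
from hypothesis import settings

from oatmask import (CyclicSCode, DetectorModel, ScanConfig,
                     build_coding_matrix, fold_to_mask)

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

TWIN_PRIME_PAIRS = [(3, 5), (5, 7), (11, 13), (17, 19)]


@pytest.fixture(scope="session")
def code15():
    return CyclicSCode.from_primes(3, 5)


@pytest.fixture(scope="session")
def W15(code15):
    return build_coding_matrix(code15)


@pytest.fixture(scope="session")
def mask15(code15):
    return fold_to_mask(code15, pitch=1.0, aperture_diameter=0.5)


@pytest.fixture(scope="session")
def detector():
    return DetectorModel()


@pytest.fixture
def scan_small():
    return ScanConfig(n_t=512)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
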