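import numpy as np
import pytest

from d4z4kit import PipelineParams
from d4z4kit.simulate import make_synthetic_bundle


@pytest.fixture(scope="session")
def bundle():
    return make_synthetic_bundle(seed=0)


@pytest.fixture(scope="session")
def dense_bundle():
    """Bundle with dense CpG planting for nucleosome-scale analyses."""
    return make_synthetic_bundle(seed=0, cpg_spacing=10)


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
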