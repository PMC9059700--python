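import numpy as np
import pytest

from fundoprep import SynthSpec, generate_fundus


@pytest.fixture(scope="session")
def centered_phantom():
    """Centered disc, r=100 on 256x256 — the canonical test image."""
    return generate_fundus(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def diseased_phantom():
    """Phantom with DR-style lesions and vessels."""
    return generate_fundus(SynthSpec(seed=21, lesion_counts={"D": 8}))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
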