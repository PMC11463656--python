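import numpy as np
import pytest

from nftseg import make_annotated_roi


@pytest.fixture(scope="session")
def clean_roi():
    """Noise-free ROI with 5 tangles and known truth, shared across tests."""
    return make_annotated_roi(5, dims=(2048, 2048), noise=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_roi():
    """ROI with diffuse DAB speckle, matching the pipeline's target data."""
    return make_annotated_roi(5, dims=(2048, 2048), noise=0.01, seed=23)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
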