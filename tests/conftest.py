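import numpy as np
import pytest

from kymovox.edge_tracking import track_edges
from kymovox.synthetic import GlottisSimParams, generate_kymogram_direct


@pytest.fixture(scope="session")
def noiseless_params():
    return GlottisSimParams(noise_sd=0.0, duration_s=0.7, seed=1)


@pytest.fixture(scope="session")
def noiseless_token(noiseless_params):
    """Noiseless synthetic kymogram plus its ground truth."""
    return generate_kymogram_direct(noiseless_params)


@pytest.fixture(scope="session")
def noiseless_vibrogram(noiseless_token):
    kym, truth = noiseless_token
    return track_edges(kym), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
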