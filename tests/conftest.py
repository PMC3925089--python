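import numpy as np
import pytest

from fluxsampler import SolutionSpace
from fluxsampler.synthetic import make_box, make_random_network, make_triangle


@pytest.fixture(scope="session")
def triangle_space() -> SolutionSpace:
    return SolutionSpace(make_triangle())


@pytest.fixture(scope="session")
def box3_space() -> SolutionSpace:
    return SolutionSpace(make_box(3, 0.0, 1.0))


@pytest.fixture(scope="session")
def network_space() -> SolutionSpace:
    """Small anisotropic random network: m=5 metabolites, n=10 reactions."""
    return SolutionSpace(make_random_network(5, 10, seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
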