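import numpy as np
import pytest

from neuroperc import LongEdgeModel, build_graph
from neuroperc.io import make_fixtures


@pytest.fixture(scope="session")
def tiny_states():
    """200 random 4x4 torus states with brute-force next states per k."""
    return make_fixtures("tiny_torus_states", seed=0)


@pytest.fixture(scope="session")
def local_graph_4():
    """4x4 torus with no long edges (c = 0)."""
    return build_graph(4, LongEdgeModel(c=0.0), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
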