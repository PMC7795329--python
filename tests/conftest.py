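import numpy as np
import pytest

from skelemo import build_upper_body_graph, make_tiny_fixture, spatial_partition


@pytest.fixture(scope="session")
def upper_graph():
    return build_upper_body_graph()


@pytest.fixture(scope="session")
def upper_adj(upper_graph):
    return spatial_partition(upper_graph)


@pytest.fixture(scope="session")
def tiny_fixture():
    """3-joint chain graph and 8 hand-written 2-frame sequences."""
    return make_tiny_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
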