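import numpy as np
import pytest

from netalign.network_io import Interaction, Interactome


def make_net(edges, species="query"):
    """Build an interactome from (a, b, reliability) triples."""
    net = Interactome(species)
    for a, b, r in edges:
        net.add_interaction(Interaction(a, b, reliability=r))
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_net():
    """a - x - b chain plus a direct a-b edge, all fully reliable."""
    return make_net([("a", "x", 1.0), ("x", "b", 1.0), ("a", "b", 1.0)])
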