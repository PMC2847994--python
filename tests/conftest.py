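import numpy as np
import pytest

from ddssa.model import Reaction, SpeciesRef, build_network


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def decay_network():
    """A -> B pure decay, k = 0.1/s."""
    a, b = SpeciesRef("A"), SpeciesRef("B")
    return build_network([a, b], [Reaction((a,), (b,), rate_k=0.1)]), a, b


@pytest.fixture
def translocation_network():
    """A_c -> A_n delayed translocation bound to the 'tau' distribution."""
    a_c, a_n = SpeciesRef("A", "c"), SpeciesRef("A", "n")
    net = build_network(
        [a_c, a_n],
        [Reaction((a_c,), (a_n,), kind="delayed", delay_source="tau")])
    return net, a_c, a_n
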