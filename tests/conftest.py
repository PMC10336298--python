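import numpy as np
import pytest

from walkformer.networks import Network, NodeVocabulary
from walkformer.synthetic import SBMSpec, generate_sbm_collection


def make_network(edges, extra_names=(), name="net"):
    """Network over the vocabulary implied by its edges plus extras."""
    names = {n for a, b, _ in edges for n in (a, b)} | set(extra_names)
    vocab = NodeVocabulary.from_names(names)
    net = Network(vocab, edges, name=name)
    net._collection_index = 0
    return net


@pytest.fixture(scope="session")
def small_sbm():
    """A quick planted-module collection for pipeline-level unit tests."""
    spec = SBMSpec(n_nodes=60, n_modules=3, p_in=0.5, p_out=0.03, T=2, dropout=0.1, seed=7)
    return generate_sbm_collection(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
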