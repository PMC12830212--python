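import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lncgat.debruijn import graph_from_sequence
from lncgat.seqio import NucleotideSequence


def random_sequence(rng: np.random.Generator, length: int, sid: str = "s") -> NucleotideSequence:
    return NucleotideSequence(sid, "".join(rng.choice(list("ACGT"), size=length)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_graph(rng):
    """A normalized De Bruijn graph from one random 60-nt sequence."""
    return graph_from_sequence(random_sequence(rng, 60), 3)


def random_graph_items(rng, n_graphs, length, d=8):
    """(features, graph, label) triples over random sequences."""
    items = []
    for i in range(n_graphs):
        g = graph_from_sequence(random_sequence(rng, length, f"g{i}"), 3)
        X = rng.normal(size=(g.n_nodes, d))
        items.append((X, g, i % 2))
    return items
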