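import numpy as np
import pytest

from chondriome._seq import random_dna
from chondriome.graph_model import AssemblyGraph, Link, Segment
from chondriome.synthetic_data import (
    IRIS_CONTIGS,
    IRIS_REPEATS,
    IRIS_TOPOLOGY,
    SimSpec,
    build_toy_graph,
)


def make_graph(lengths: dict, repeats: set, topology, seed=0, gc=0.45) -> AssemblyGraph:
    """Graph with random sequences of the given lengths; multiplicity 2 for
    ids in ``repeats``."""
    rng = np.random.default_rng(seed)
    g = AssemblyGraph()
    for sid in sorted(lengths):
        g.add_segment(
            Segment(sid, random_dna(rng, lengths[sid], gc), multiplicity=2 if sid in repeats else 1)
        )
    for a, b in topology:
        g.add_link(Link(a, "+", b, "+", 0))
    return g


@pytest.fixture(scope="session")
def iris_graph_small():
    """The two-repeat four-contig toy graph at 1/100 scale with its labelled
    conformation ground truth."""
    return build_toy_graph(SimSpec.iris(seed=1))


@pytest.fixture(scope="session")
def iris_graph_full():
    """Same topology at the published full-scale segment lengths."""
    return make_graph(
        {**IRIS_CONTIGS, **IRIS_REPEATS}, set(IRIS_REPEATS), IRIS_TOPOLOGY, seed=1, gc=0.465
    )
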