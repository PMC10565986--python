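import numpy as np
import pytest

from drivernet import gnn, graph_io, synth


@pytest.fixture(scope="session")
def block_graph():
    """60-gene, 2-block, 2-relation synthetic interaction graph."""
    return synth.simulate_graph(synth.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def toy_graph():
    """Tiny 2-relation graph for hand-computable checks."""
    binds = graph_io.RelationLabel("binds", "toy")
    controls = graph_io.RelationLabel("controls", "toy")
    return graph_io.KnowledgeGraph.build(
        [
            ("A", binds, "B"),
            ("B", binds, "C"),
            ("A", controls, "C"),
            ("C", controls, "D"),
        ]
    )


@pytest.fixture(scope="session")
def pretrained(block_graph):
    """One shared desk-scale pretraining run (lr scaled up for tiny graphs)."""
    config = gnn.GnnConfig(dim=16, epochs=50, learning_rate=0.01, seed=7)
    params, table, trace = gnn.pretrain(block_graph, config)
    return config, params, table, trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
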