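import numpy as np
import pytest

from ddegk.divergence import EncoderConfig
from ddegk.graphs import EdgeRecord, EventGraph, NodeRecord, TypeVocabulary
from ddegk.synth import default_schema, generate


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_graphs(schema):
    graphs, labels = generate(schema, 12, seed=2)
    return graphs, labels


@pytest.fixture(scope="session")
def vocab(small_graphs):
    return TypeVocabulary.from_graphs(small_graphs[0])


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced-epoch config for unit tests where convergence quality is
    not the property under test."""
    return EncoderConfig(encoding_epochs=80, scoring_epochs=80)


@pytest.fixture
def minimal_graph():
    """Smallest valid event: trigger --Theme--> entity."""
    return EventGraph(
        nodes=[NodeRecord("T2", "trigger", "Gene_expression", "expression"),
               NodeRecord("T1", "entity", "Protein", "Bmi-1")],
        edges=[EdgeRecord("T2", "T1", "Theme")],
        root_id="T2", principal_type="Gene_expression", doc_id="mini")


@pytest.fixture
def nested_graph():
    """Two nested events: a gene-expression root whose Cause argument is a
    positive-regulation sub-event (4 nodes, 3 edges)."""
    return EventGraph(
        nodes=[NodeRecord("T2", "trigger", "Gene_expression", "expression"),
               NodeRecord("T1", "entity", "Protein", "Bmi-1"),
               NodeRecord("T3", "trigger", "Positive_regulation", "promote"),
               NodeRecord("T4", "entity", "Cancer", "tumorigenesis")],
        edges=[EdgeRecord("T2", "T1", "Theme"),
               EdgeRecord("T2", "T3", "Cause"),
               EdgeRecord("T3", "T4", "Theme")],
        root_id="T2", principal_type="Gene_expression", doc_id="nested")


@pytest.fixture
def nested_vocab(nested_graph, minimal_graph):
    return TypeVocabulary.from_graphs([nested_graph, minimal_graph])


def random_graph(rng: np.random.Generator, n_nodes: int) -> EventGraph:
    """Random rooted DAG used by property tests: node 0 is the root trigger,
    every later node attaches to an earlier trigger."""
    roles = ["Theme", "Cause", "Site"]
    nodes = [NodeRecord("n0", "trigger", "Ev", "root")]
    edges = []
    triggers = [0]
    for i in range(1, n_nodes):
        is_trigger = rng.random() < 0.4
        kind = "trigger" if is_trigger else "entity"
        nodes.append(NodeRecord(f"n{i}", kind, "Ev" if is_trigger else "Ent",
                                f"w{i}"))
        parent = int(rng.choice(triggers))
        edges.append(EdgeRecord(f"n{parent}", f"n{i}",
                                roles[int(rng.integers(len(roles)))]))
        if is_trigger:
            triggers.append(i)
    return EventGraph(nodes, edges, "n0", "Ev", doc_id=f"rand{n_nodes}")
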