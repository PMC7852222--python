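import networkx as nx
import numpy as np
import pytest

from genewalk.assembly import OntologyTerm


def make_ontology(edges, namespace="biological_process", extra=()):
    """Build an ontology dict from (child, parent) is_a pairs."""
    parents = {}
    nodes = set(extra)
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        nodes |= {child, parent}
    return {
        n: OntologyTerm(
            go_id=n, name=f"term {n}", namespace=namespace,
            parent_ids=frozenset(parents.get(n, ())),
        )
        for n in nodes
    }


@pytest.fixture
def toy_ontology():
    """Root r with children t1, t2 (the 3-term ontology of the worked example)."""
    return make_ontology([("GO:0000002", "GO:0000001"),
                          ("GO:0000003", "GO:0000001")])


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A")])
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(0)
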