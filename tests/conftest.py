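import networkx as nx
import pytest

from mirlink.ontology import OntologyDag, information_content


def dag_from_edges(edges, nodes=()):
    """Build an OntologyDag from child->parent edge pairs."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return OntologyDag(graph=g, namespace="biological_process")


@pytest.fixture
def seven_term_dag():
    """root with children A, B; A has leaves A1, A2; B has leaves B1, B2."""
    return dag_from_edges(
        [
            ("A", "root"),
            ("B", "root"),
            ("A1", "A"),
            ("A2", "A"),
            ("B1", "B"),
            ("B2", "B"),
        ]
    )


@pytest.fixture
def seven_term_ic(seven_term_dag):
    return information_content(seven_term_dag)
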