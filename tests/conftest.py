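import networkx as nx
import numpy as np
import pytest

from string2go import (OntologyDAG, SyntheticSpec, WeightedNetwork,
                       simulate_network, simulate_ontology_annotations)


def make_network(edges, name="combinedscore"):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return WeightedNetwork(graph=g, name=name)


def make_dag(edges, extra_terms=()):
    """DAG from (child, parent) is_a pairs."""
    dag = OntologyDAG()
    for child, parent in edges:
        dag.parents.add_edge(child, parent)
    for t in extra_terms:
        dag.parents.add_node(t)
    return dag


@pytest.fixture
def chain_dag():
    # t3 is_a t2 is_a t1
    return make_dag([("t3", "t2"), ("t2", "t1")])


@pytest.fixture
def diamond_dag():
    # t4 is_a {t2, t3}, both is_a t1
    return make_dag([("t4", "t2"), ("t4", "t3"), ("t2", "t1"), ("t3", "t1")])


@pytest.fixture
def triangle_pendant():
    return make_network([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                         ("c", "d", 1.0)])


@pytest.fixture(scope="session")
def small_synthetic():
    """Small community-structured fixture shared by slower tests."""
    spec = SyntheticSpec(n_proteins=90, k_communities=3, seed=0)
    net, assign = simulate_network(spec)
    dag, ann, leaves = simulate_ontology_annotations(spec, assign)
    return {"spec": spec, "net": net, "assign": assign, "dag": dag,
            "ann": ann, "leaves": leaves}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
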