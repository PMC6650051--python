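"""Desk-scale synthetic testbed with planted guilt-by-association structure.

The generator emits exactly the formats the pipeline reads: a
community-structured weighted network (planted partition), a toy GO-like
DAG with per-community leaf terms, community-correlated annotations, and a
synthetic homology hit table.  Within-community edges are denser and
heavier than between-community edges, and proteins preferentially carry
their community's terms — the "interacting proteins share function"
premise the method relies on, in its simplest expressible form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import WeightedNetwork
from .ontology import (AnnotationMatrix, OntologyDAG, propagate_annotations)

logger = logging.getLogger(__name__)

#: annotations carry this evidence code so the default filter accepts them
_EVIDENCE = "EXP"


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Defaults: 300 proteins in 3 communities, within/between edge
    probabilities 0.3 / 0.02, annotation true-positive rate 0.9 and
    background rate 0.05, 2 leaf terms per community under a depth-3 chain
    DAG — strong but noisy guilt-by-association signal at desk scale.
    """

    n_proteins: int = 300
    k_communities: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    weight_noise: float = 0.05
    n_terms: int = 6
    terms_per_community: int = 2
    annotation_tpr: float = 0.9
    annotation_fpr: float = 0.05
    dag_depth: int = 3
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not (0 <= self.p_out <= self.p_in <= 1):
            problems.append("need 0 <= p_out <= p_in <= 1")
        if not (0 <= self.annotation_tpr <= 1
                and 0 <= self.annotation_fpr <= 1):
            problems.append("annotation rates must lie in [0, 1]")
        if self.n_proteins < self.k_communities:
            problems.append("need n_proteins >= k_communities")
        if self.dag_depth < 1 or self.terms_per_community < 1:
            problems.append("dag_depth and terms_per_community must be >= 1")
        if problems:
            raise ValueError("invalid synthetic spec: " + "; ".join(problems))


def community_assignment(spec: SyntheticSpec) -> dict[str, int]:
    """Round-robin-free contiguous assignment: protein p0..p(n-1), community
    i gets the i-th block of ceil(n/k) proteins."""
    block = math.ceil(spec.n_proteins / spec.k_communities)
    return {f"p{i:04d}": min(i // block, spec.k_communities - 1)
            for i in range(spec.n_proteins)}


def simulate_network(spec: SyntheticSpec) -> tuple[WeightedNetwork, dict[str, int]]:
    """Planted-partition graph with heavier within-community weights.

    Within-community edges appear with probability p_in and weight
    clip(0.8 + N(0, weight_noise), 0.01, 1); between-community edges with
    probability p_out and weight clip(0.3 + noise, 0.01, 1).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    assign = community_assignment(spec)
    nodes = list(assign)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            same = assign[u] == assign[v]
            if rng.random() < (spec.p_in if same else spec.p_out):
                base = 0.8 if same else 0.3
                w = float(np.clip(base + rng.normal(0, spec.weight_noise),
                                  0.01, 1.0))
                g.add_edge(u, v, weight=w)
    return WeightedNetwork(graph=g, name="synthetic"), assign


def toy_dag(spec: SyntheticSpec) -> tuple[OntologyDAG, dict[int, list[str]]]:
    """One root, then per community ``terms_per_community`` is_a chains of
    length ``dag_depth`` ending in a leaf term.  Returns the DAG and the
    leaf terms assigned to each community."""
    dag = OntologyDAG()
    root = "T:root"
    dag.parents.add_node(root)
    dag.namespace[root] = "biological_process"
    community_leaves: dict[int, list[str]] = {}
    for c in range(spec.k_communities):
        leaves = []
        for t in range(spec.terms_per_community):
            parent = root
            for depth in range(1, spec.dag_depth + 1):
                term = f"T:c{c}t{t}d{depth}"
                dag.parents.add_node(term)
                dag.namespace[term] = "biological_process"
                dag.parents.add_edge(term, parent)
                parent = term
            leaves.append(parent)
        community_leaves[c] = leaves
    return dag, community_leaves


def simulate_ontology_annotations(
    spec: SyntheticSpec, assignment: dict[str, int]
) -> tuple[OntologyDAG, AnnotationMatrix, dict[int, list[str]]]:
    """Community-correlated annotations over the toy DAG, propagated.

    Each protein receives each of its community's leaf terms with
    probability ``annotation_tpr`` and each foreign leaf with probability
    ``annotation_fpr``.  The returned matrix is is_a-propagated; proteins
    that drew no term at all are absent (consistent with the evidence
    filter contract).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    dag, community_leaves = toy_dag(spec)
    triples = []
    for protein in sorted(assignment):
        own = assignment[protein]
        for c, leaves in community_leaves.items():
            prob = spec.annotation_tpr if c == own else spec.annotation_fpr
            for leaf in leaves:
                if rng.random() < prob:
                    triples.append((protein, leaf, _EVIDENCE))
    if not triples:
        logger.warning("no protein drew any annotation; matrix is empty")
        ann = AnnotationMatrix(labels=pd.DataFrame(dtype="int8"))
    else:
        ann = propagate_annotations(triples, dag)
    return dag, ann, community_leaves


def simulate_homology(eval_ids, train_ids, clone_fraction: float,
                      seed: int = 0) -> list[tuple[str, str, float]]:
    """Synthetic homology hit table feeding homolog removal.

    Designates ceil(clone_fraction * n_eval) evaluation proteins as having
    a training-set homolog, with E-values log-uniform in [1e-10, 1e-1].
    """
    if not (0.0 <= clone_fraction <= 1.0):
        raise ValueError("clone_fraction must lie in [0, 1]")
    eval_ids = list(eval_ids)
    train_ids = list(train_ids)
    rng = np.random.default_rng(seed)
    n_pairs = math.ceil(clone_fraction * len(eval_ids))
    if n_pairs == 0 or not train_ids:
        return []
    chosen = rng.choice(len(eval_ids), size=n_pairs, replace=False)
    table = []
    for idx in sorted(chosen):
        subject = train_ids[rng.integers(len(train_ids))]
        evalue = 10.0 ** rng.uniform(-10, -1)
        table.append((eval_ids[idx], subject, float(evalue)))
    return table


def write_homology_tsv(table, path) -> None:
    with open(path, "w") as fh:
        for q, s, e in table:
            fh.write(f"{q}\t{s}\t{e:.6g}\n")


def write_annotation_tsv(triples, path) -> None:
    with open(path, "w") as fh:
        for protein, term, evidence in triples:
            fh.write(f"{protein}\t{term}\t{evidence}\n")


def write_obo(dag: OntologyDAG, path) -> None:
    """Emit a minimal OBO 1.2 file for the toy DAG (round-trips via parse_obo)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.parents.nodes):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            ns = dag.namespace.get(term, "biological_process")
            fh.write(f"namespace: {ns}\n")
            for parent in sorted(dag.parents.successors(term)):
                fh.write(f"is_a: {parent} ! {parent}\n")
            fh.write("\n")
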