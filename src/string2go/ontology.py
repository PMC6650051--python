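"""Gene Ontology handling: OBO parsing, is_a propagation, vocabulary selection.

Annotations obey the true-path rule: a protein annotated with a term is
implicitly annotated with every ancestor reachable over ``is_a``.  The
prediction vocabulary keeps only sufficiently frequent terms that have no
retained descendant (the deepest-term antichain), so predictions stay
specific and informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: GO evidence codes counted as experimental support.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


class OntologyError(ValueError):
    pass


class OntologyCycleError(OntologyError):
    """is_a graph contains a cycle (lists one offending cycle)."""


class EmptyAnnotationError(OntologyError):
    """No annotation survived evidence/term filtering."""


@dataclass
class OntologyDAG:
    """GO DAG restricted to non-obsolete terms and is_a links.

    ``parents`` holds child -> parent edges (the direction of is_a).
    """

    parents: nx.DiGraph = field(default_factory=nx.DiGraph)
    namespace: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.parents.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> set[str]:
        """Strict is_a ancestors of ``term``."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        return nx.descendants(self.parents, term)  # edges point child -> parent

    def descendants(self, term: str) -> set[str]:
        """Strict is_a descendants of ``term``."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        return nx.ancestors(self.parents, term)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.parents):
            cycle = nx.find_cycle(self.parents)
            raise OntologyCycleError(f"is_a graph is cyclic: {cycle}")


def parse_obo(path, namespaces: Sequence[str] | None = None) -> OntologyDAG:
    """Read an OBO 1.2 file into an :class:`OntologyDAG`.

    Only ``is_a`` links between non-obsolete terms are kept; other
    relationship types (part_of, regulates, ...) are ignored.  A cyclic
    is_a graph raises :class:`OntologyCycleError`.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    dag = OntologyDAG()
    for term, data in multigraph.nodes(data=True):
        ns = data.get("namespace", "")
        if namespaces and ns not in namespaces:
            continue
        dag.parents.add_node(term)
        dag.namespace[term] = ns
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if child in dag.parents and parent in dag.parents:
            dag.parents.add_edge(child, parent)
    dag.validate()
    return dag


@dataclass
class AnnotationMatrix:
    """Binary protein x term incidence, closed under is_a propagation."""

    labels: pd.DataFrame  # index: proteins, columns: terms, dtype int8
    accepted_evidence: frozenset[str] = EXPERIMENTAL_EVIDENCE

    @property
    def proteins(self) -> list[str]:
        return list(self.labels.index)

    @property
    def terms(self) -> list[str]:
        return list(self.labels.columns)

    def annotated(self, protein: str) -> set[str]:
        row = self.labels.loc[protein]
        return set(row.index[row > 0])

    def term_counts(self) -> pd.Series:
        return self.labels.sum(axis=0)

    def restrict_terms(self, terms: Sequence[str]) -> "AnnotationMatrix":
        cols = [t for t in terms if t in self.labels.columns]
        missing = [t for t in terms if t not in self.labels.columns]
        out = self.labels[cols].copy()
        for t in missing:
            out[t] = 0
        return AnnotationMatrix(labels=out[list(terms)].astype("int8"),
                                accepted_evidence=self.accepted_evidence)

    def restrict_proteins(self, proteins: Sequence[str]) -> "AnnotationMatrix":
        out = self.labels.reindex(index=list(proteins), fill_value=0)
        return AnnotationMatrix(labels=out.astype("int8"),
                                accepted_evidence=self.accepted_evidence)


def propagate_annotations(
    raw: Iterable[tuple[str, str, str]],
    dag: OntologyDAG,
    accepted_evidence: Iterable[str] = EXPERIMENTAL_EVIDENCE,
) -> AnnotationMatrix:
    """Evidence-filter direct annotations and close them over is_a.

    ``raw`` yields (protein, term, evidence_code) triples.  Terms absent
    from the DAG are dropped with a warning; proteins with no accepted
    annotation are excluded.  Raises :class:`EmptyAnnotationError` when
    nothing survives.
    """
    accepted = frozenset(accepted_evidence)
    direct: dict[str, set[str]] = {}
    n_unknown = 0
    for protein, term, evidence in raw:
        if evidence not in accepted:
            continue
        if term not in dag:
            n_unknown += 1
            continue
        direct.setdefault(protein, set()).add(term)
    if n_unknown:
        logger.warning("dropped %d annotations with terms absent from the DAG",
                       n_unknown)
    if not direct:
        raise EmptyAnnotationError(
            "no annotations left after evidence/term filtering"
        )
    closure_cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in closure_cache:
            closure_cache[term] = {term} | dag.ancestors(term)
        return closure_cache[term]

    rows = {}
    all_terms: set[str] = set()
    for protein, terms in direct.items():
        closed: set[str] = set()
        for t in terms:
            closed |= closure(t)
        rows[protein] = closed
        all_terms |= closed
    term_order = sorted(all_terms)
    proteins = sorted(rows)
    labels = pd.DataFrame(0, index=proteins, columns=term_order, dtype="int8")
    for protein, closed in rows.items():
        labels.loc[protein, sorted(closed)] = 1
    return AnnotationMatrix(labels=labels, accepted_evidence=accepted)


def read_annotation_tsv(path) -> list[tuple[str, str, str]]:
    """Read a GAF-like TSV of (protein_id, go_id, evidence_code) rows."""
    triples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise OntologyError(
                    f"line {lineno}: expected 3 tab-separated columns"
                )
            triples.append((parts[0], parts[1], parts[2]))
    return triples


@dataclass
class TermVocabulary:
    """Deepest-term antichain of sufficiently frequent terms."""

    terms: list[str]
    min_count: int = 100

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)


def select_term_vocabulary(
    ann: AnnotationMatrix, dag: OntologyDAG, min_count: int = 100
) -> TermVocabulary:
    """Frequency-filter terms, then keep only those with no candidate descendant.

    Candidates are terms annotating at least ``min_count`` proteins in the
    (propagated) annotation matrix.  A candidate is retained iff no other
    candidate is a strict is_a descendant, i.e. the retained set is the
    maximal-depth antichain of the candidate set.  Order is lexicographic.
    """
    counts = ann.term_counts()
    candidates = sorted(t for t in counts.index
                        if counts[t] >= min_count and t in dag)
    cand_set = set(candidates)
    retained = [t for t in candidates if not (dag.descendants(t) & cand_set)]
    if not retained:
        logger.warning("vocabulary is empty at min_count=%d", min_count)
    return TermVocabulary(terms=retained, min_count=min_count)


def term_descendants(dag: OntologyDAG, term: str) -> set[str]:
    """Strict is_a descendants of ``term`` (the term itself excluded)."""
    return dag.descendants(term)
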