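"""Training / hold-out / temporal splits and homolog removal.

Hold-out proteins are sampled from well-annotated entries (minimum term
counts per ontology branch); temporal-validation proteins are those with no
vocabulary annotation at the training snapshot that gained at least one by
a later snapshot.  Homolog removal drops evaluation proteins with any
training homolog at or below an E-value threshold — a larger threshold is a
wider homology definition and removes more proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationMatrix, TermVocabulary

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train: list[str]
    holdout: list[str]
    temporal: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if set(self.train) & set(self.holdout):
            raise ValueError("train and holdout overlap")
        if set(self.train) & set(self.temporal):
            raise ValueError("train and temporal overlap")
        for name, ids in (("train", self.train), ("holdout", self.holdout),
                          ("temporal", self.temporal)):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate ids in {name} set")


class HomologyOracle:
    """Answers evalue(query, subject) from a precomputed hit table.

    The backing table is TSV with at least (query, subject, evalue);
    12-column BLAST tabular output is accepted, extra columns ignored.
    ``symmetric=True`` also answers for swapped (subject, query) pairs.
    """

    def __init__(self, hits: dict[tuple[str, str], float] | None = None,
                 symmetric: bool = True):
        self.hits = dict(hits or {})
        self.symmetric = symmetric
        for (q, s), e in self.hits.items():
            if e <= 0:
                raise ValueError(f"E-value must be positive for ({q}, {s})")

    @classmethod
    def from_tsv(cls, path, symmetric: bool = True) -> "HomologyOracle":
        hits: dict[tuple[str, str], float] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or line.startswith("#"):
                    continue
                q, s = parts[0], parts[1]
                # BLAST outfmt 6 carries the E-value in column 11 (0-based 10)
                e = float(parts[10]) if len(parts) >= 12 else float(parts[2])
                key = (q, s)
                if key not in hits or e < hits[key]:
                    hits[key] = e
        return cls(hits=hits, symmetric=symmetric)

    def evalue(self, query: str, subject: str) -> float | None:
        e = self.hits.get((query, subject))
        if e is None and self.symmetric:
            e = self.hits.get((subject, query))
        return e

    def best_hit(self, query: str, subjects) -> float | None:
        best = None
        for s in subjects:
            e = self.evalue(query, s)
            if e is not None and (best is None or e < best):
                best = e
        return best


def make_holdout_split(ann: AnnotationMatrix,
                       min_terms: int | dict[str, int] = 1,
                       holdout_size: int = 1000, seed: int = 0,
                       branch_counts: dict[str, np.ndarray] | None = None
                       ) -> SplitSpec:
    """Seeded uniform hold-out sample from well-annotated proteins.

    ``min_terms`` is either a single minimum annotation count over the
    matrix's terms, or per-branch minima (e.g. {"BP": 28, "MF": 5,
    "CC": 14}) checked against ``branch_counts`` — a mapping from branch
    name to a per-protein annotation-count vector aligned with
    ``ann.proteins``.  If fewer proteins qualify than ``holdout_size``, all
    of them are taken with a warning.
    """
    proteins = np.array(ann.proteins)
    if isinstance(min_terms, dict):
        if branch_counts is None:
            raise ValueError("per-branch minima require branch_counts")
        ok = np.ones(len(proteins), dtype=bool)
        for branch, minimum in min_terms.items():
            ok &= np.asarray(branch_counts[branch]) >= minimum
    else:
        ok = ann.labels.to_numpy().sum(axis=1) >= min_terms
    eligible = proteins[ok]
    if len(eligible) == 0:
        logger.warning("no protein satisfies the well-annotated rule; "
                       "hold-out is empty")
        holdout: list[str] = []
    elif len(eligible) < holdout_size:
        logger.warning("only %d proteins qualify (< %d requested); taking all",
                       len(eligible), holdout_size)
        holdout = sorted(eligible)
    else:
        rng = np.random.default_rng(seed)
        holdout = sorted(rng.choice(eligible, size=holdout_size,
                                    replace=False))
    holdout_set = set(holdout)
    train = [p for p in proteins if p not in holdout_set]
    spec = SplitSpec(train=train, holdout=list(holdout), seed=seed)
    spec.validate()
    return spec


def make_temporal_split(ann_t0: AnnotationMatrix, ann_t1: AnnotationMatrix,
                        vocab: TermVocabulary) -> list[str]:
    """Proteins with zero vocabulary annotations at t0 and >= 1 at t1."""
    terms = list(vocab)
    y0 = ann_t0.restrict_terms(terms).labels
    y1 = ann_t1.restrict_terms(terms).labels
    out = []
    for p in y1.index:
        gained = y1.loc[p].sum() > 0
        had = p in y0.index and y0.loc[p].sum() > 0
        if gained and not had:
            out.append(p)
    return sorted(out)


def homolog_removal(eval_ids, train_ids, oracle: HomologyOracle,
                    evalue_threshold: float) -> list[str]:
    """Drop evaluation proteins with any training homolog at E <= threshold."""
    if evalue_threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    train_list = list(train_ids)
    kept = []
    for p in eval_ids:
        best = oracle.best_hit(p, train_list)
        if best is None or best > evalue_threshold:
            kept.append(p)
    return kept


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
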