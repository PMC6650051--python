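"""End-to-end orchestration: embed -> maxout training/extraction -> heads -> evaluate.

The three-stage flow mirrors the method: (1) embed the PPI network,
(2) train the deep maxout network on the training proteins' vocabulary
labels and extract third-hidden-layer functional representations,
(3) score evaluation proteins with a per-term SVM head (on the raw
embedding or the functional representation), the network's own sigmoid
head, or a baseline, and evaluate everything through the same report path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .classifiers import (NaiveFrequencyBaseline, PPIHomologBaseline,
                          TermSVMStack)
from .dmnn import DeepMaxoutClassifier, DMNNConfig, _cfg_kwargs, \
    extract_representation
from .embedding import (EmbeddingMatrix, MashupEmbedding, Node2VecEmbedding)
from .evaluation import EvaluationReport, evaluate_scores, lower_median, \
    paired_tests
from .network import WeightedNetwork, read_string_edgelist
from .ontology import (AnnotationMatrix, OntologyDAG, TermVocabulary,
                       parse_obo, propagate_annotations, read_annotation_tsv,
                       select_term_vocabulary)
from .splits import HomologyOracle, read_id_list

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    network_path: str = ""
    obo_path: str = ""
    annotation_path: str = ""
    train_ids_path: str = ""
    eval_ids_path: str = ""
    homology_path: str = ""
    embedding_method: str = "node2vec"  # node2vec | mashup
    embedding_params: dict = field(default_factory=dict)
    dmnn: DMNNConfig = field(default_factory=DMNNConfig)
    head: str = "svm"  # svm | sigmoid | naive | ppi-homolog | raw-svm
    svm_folds: int = 10
    min_count: int = 100
    evalue_threshold: float = 1e-2
    seed: int = 0
    outdir: str = "string2go_run"

    def validate(self) -> None:
        for label, p in (("network", self.network_path),
                         ("obo", self.obo_path),
                         ("annotations", self.annotation_path)):
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.head not in ("svm", "sigmoid", "naive", "ppi-homolog",
                             "raw-svm"):
            raise ValueError(f"unknown head {self.head!r}")


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def embed_network(net: WeightedNetwork, method: str, params: dict,
                  seed: int) -> EmbeddingMatrix:
    if method == "mashup":
        est = MashupEmbedding(**params)
    elif method == "node2vec":
        est = Node2VecEmbedding(seed=seed, **params)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    try:
        return est.fit_transform(net)
    except Exception as exc:  # pragma: no cover - stage naming
        raise StageError(f"embedding stage failed: {exc}") from exc


@dataclass
class StudyResult:
    """Scores and evaluation reports of every requested head on one run."""

    reports: dict[str, EvaluationReport]
    scores: dict[str, np.ndarray]
    truth: np.ndarray
    eval_proteins: list[str]
    vocab: TermVocabulary
    raw_embedding: EmbeddingMatrix | None = None
    functional: EmbeddingMatrix | None = None
    dmnn_model: DeepMaxoutClassifier | None = None


def run_study(
    net: WeightedNetwork,
    dag: OntologyDAG,
    ann: AnnotationMatrix,
    vocab: TermVocabulary,
    train_ids: list[str],
    eval_ids: list[str],
    heads=("svm", "raw-svm", "sigmoid", "naive"),
    embedding_method: str = "node2vec",
    embedding_params: dict | None = None,
    dmnn_cfg: DMNNConfig | None = None,
    svm_grid: tuple | None = None,
    svm_folds: int = 10,
    homology: HomologyOracle | None = None,
    evalue_threshold: float = 1e-2,
    seed: int = 0,
    eval_truth: AnnotationMatrix | None = None,
) -> StudyResult:
    """Run the full method and requested baselines on one dataset.

    ``ann`` supplies training labels; ``eval_truth`` (default ``ann``)
    supplies evaluation labels, so temporal validation can pass a later
    snapshot.  Evaluation is restricted to eval proteins carrying at least
    one vocabulary annotation in the truth.
    """
    dmnn_cfg = dmnn_cfg or DMNNConfig(seed=seed)
    eval_truth = eval_truth if eval_truth is not None else ann
    terms = list(vocab)
    if not terms:
        raise StageError("evaluation stage failed: empty vocabulary")

    raw = embed_network(net, embedding_method,
                        dict(embedding_params or {}), seed)
    row = {p: i for i, p in enumerate(raw.proteins)}

    train_use = [p for p in train_ids if p in row and p in ann.labels.index]
    if not train_use:
        raise StageError("training stage failed: no train protein has both "
                         "an embedding and annotations")
    Y_train = ann.restrict_terms(terms).restrict_proteins(train_use)
    X_train = raw.vectors[[row[p] for p in train_use]]

    truth_full = eval_truth.restrict_terms(terms)
    eval_use = [p for p in eval_ids if p in row
                and p in truth_full.labels.index
                and truth_full.labels.loc[p].sum() > 0]
    if not eval_use:
        raise StageError("evaluation stage failed: no eval protein has an "
                         "embedding and >= 1 vocabulary annotation")
    truth = truth_full.restrict_proteins(eval_use).labels.to_numpy()
    X_eval_raw = raw.vectors[[row[p] for p in eval_use]]

    model = None
    functional = None
    needs_dmnn = any(h in ("svm", "sigmoid") for h in heads)
    if needs_dmnn:
        try:
            model = DeepMaxoutClassifier(**_cfg_kwargs(dmnn_cfg))
            model.fit(X_train, Y_train.labels.to_numpy())
            functional = extract_representation(model, raw)
        except Exception as exc:
            raise StageError(f"dmnn stage failed: {exc}") from exc

    svm_kwargs = {"folds": svm_folds, "seed": seed}
    if svm_grid is not None:
        svm_kwargs["c_grid"], svm_kwargs["gamma_grid"] = svm_grid

    scores: dict[str, np.ndarray] = {}
    train_ann_vocab = Y_train
    for head in heads:
        try:
            if head == "svm":
                stack = TermSVMStack(**svm_kwargs)
                X_func_train = functional.vectors[[row[p] for p in train_use]]
                stack.fit(X_func_train, train_ann_vocab, vocab=vocab, dag=dag)
                X_func_eval = functional.vectors[[row[p] for p in eval_use]]
                scores[head] = stack.predict_proba(X_func_eval)
            elif head == "raw-svm":
                stack = TermSVMStack(**svm_kwargs)
                stack.fit(X_train, train_ann_vocab, vocab=vocab, dag=dag)
                scores[head] = stack.predict_proba(X_eval_raw)
            elif head == "sigmoid":
                scores[head] = model.predict_proba(X_eval_raw)
            elif head == "naive":
                nb = NaiveFrequencyBaseline().fit(train_ann_vocab, vocab)
                scores[head] = nb.predict_proba(eval_use)
            elif head == "ppi-homolog":
                if homology is None:
                    raise ValueError("ppi-homolog head needs a homology oracle")
                ph = PPIHomologBaseline(evalue_threshold=evalue_threshold)
                ph.fit(net, train_ann_vocab, homology, vocab=vocab)
                scores[head] = ph.predict_proba(eval_use)
            else:
                raise ValueError(f"unknown head {head!r}")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"{head} head failed: {exc}") from exc

    reports = {h: evaluate_scores(h, s, truth, terms)
               for h, s in scores.items()}
    return StudyResult(reports=reports, scores=scores, truth=truth,
                       eval_proteins=eval_use, vocab=vocab,
                       raw_embedding=raw, functional=functional,
                       dmnn_model=model)


def run_pipeline(cfg: RunConfig) -> StudyResult:
    """File-based end-to-end run with persisted, provenance-stamped artifacts."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        net = read_string_edgelist(cfg.network_path)
        dag = parse_obo(cfg.obo_path)
        triples = read_annotation_tsv(cfg.annotation_path)
        ann = propagate_annotations(triples, dag)
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc
    vocab = select_term_vocabulary(ann, dag, min_count=cfg.min_count)
    if cfg.train_ids_path:
        train_ids = read_id_list(cfg.train_ids_path)
    else:
        train_ids = list(ann.proteins)
    if cfg.eval_ids_path:
        eval_ids = read_id_list(cfg.eval_ids_path)
    else:
        eval_ids = list(ann.proteins)
    homology = (HomologyOracle.from_tsv(cfg.homology_path)
                if cfg.homology_path else None)
    head_map = {"svm": ("svm",), "sigmoid": ("sigmoid",),
                "naive": ("naive",), "ppi-homolog": ("ppi-homolog",),
                "raw-svm": ("raw-svm",)}
    result = run_study(
        net, dag, ann, vocab, train_ids, eval_ids,
        heads=head_map[cfg.head],
        embedding_method=cfg.embedding_method,
        embedding_params=cfg.embedding_params,
        dmnn_cfg=cfg.dmnn, svm_folds=cfg.svm_folds,
        homology=homology, evalue_threshold=cfg.evalue_threshold,
        seed=cfg.seed,
    )
    _persist(cfg, result, outdir)
    return result


def _persist(cfg: RunConfig, result: StudyResult, outdir: Path) -> None:
    meta = {
        "seed": cfg.seed,
        "head": cfg.head,
        "embedding_method": cfg.embedding_method,
        "embedding_params": cfg.embedding_params,
        "dmnn": asdict(cfg.dmnn),
        "inputs": {},
    }
    for label, p in (("network", cfg.network_path), ("obo", cfg.obo_path),
                     ("annotations", cfg.annotation_path)):
        if p:
            meta["inputs"][label] = {"path": str(p), "sha256": _file_hash(p)}
    if result.raw_embedding is not None:
        result.raw_embedding.to_tsv(outdir / "embedding.tsv")
    if result.functional is not None:
        result.functional.to_tsv(outdir / "functional_representation.tsv")
    for head, s in result.scores.items():
        write_predictions(result.eval_proteins, list(result.vocab), s,
                          outdir / f"predictions_{head}.tsv")
    summary = {}
    for head, rep in result.reports.items():
        summary[head] = {
            "median_f1": rep.median_f1, "median_mcc": rep.median_mcc,
            "median_auprc": rep.median_auprc, "fmax": rep.fmax,
            "tau_star": rep.tau_star, "f_tau": rep.f_tau,
        }
        rep.to_frame().to_csv(outdir / f"per_term_{head}.tsv", sep="\t",
                              index=False)
    meta["summary"] = summary
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def write_predictions(proteins, terms, scores, path) -> None:
    """CAFA-style prediction TSV: protein_id, term_id, score (3 decimals)."""
    with open(path, "w") as fh:
        for i, p in enumerate(proteins):
            for j, t in enumerate(terms):
                fh.write(f"{p}\t{t}\t{scores[i, j]:.3f}\n")


def compare_runs(reports: dict[str, EvaluationReport],
                 metric: str = "f1") -> dict:
    """Side-by-side medians plus paired significance tests across methods."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    term_lists = {tuple(r.terms) for r in reports.values()}
    if len(term_lists) != 1:
        raise ValueError("reports do not share the term vocabulary")
    vectors = {name: getattr(r, metric) for name, r in reports.items()}
    medians = {name: lower_median(v) for name, v in vectors.items()}
    tests = paired_tests(vectors)
    return {"metric": metric, "medians": medians, "tests": tests,
            "n_terms": len(next(iter(reports.values())).terms)}
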