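# string2go

Protein function prediction from protein–protein interaction (PPI)
networks. The package is for computational biologists who have a
STRING-style weighted network and experimentally supported Gene Ontology
(GO) annotations, and want calibrated per-term predictions for the
biological-process branch, evaluated the way the function-prediction
community (CAFA) evaluates them.

## The method

Interacting proteins tend to share function. `string2go` turns that
premise into a three-stage learning procedure:

1. **Embed the network.** Either diffusion states from random walks with
   restart, `S = r(I − (1−r)P)⁻¹`, compressed by truncated SVD to
   `U_d√Σ_d` (Mashup-style, restart 0.5, 800 dims), or second-order
   biased random walks (length 10, in-out parameter q = 2) fed to a
   skip-gram model (node2vec-style, 32–512 dims).
2. **Learn functional representations.** A deep maxout neural network
   (3 hidden blocks of batch-norm → 3-piece maxout → dropout; sigmoid
   output per vocabulary term; AdaGrad, lr 0.05, batch 100, 150 epochs)
   is trained to predict all of a protein's GO terms at once. The third
   hidden layer's activations, taken in inference mode, are features
   that encode both the interaction neighborhood and term co-occurrence.
3. **Classify per term.** One RBF-kernel SVM per vocabulary term
   (positives: proteins annotated with the term or an is_a descendant),
   grid-searched by stratified-CV F1 and Platt-calibrated to posteriors
   in [0, 1]. The network's own sigmoid layer is an alternative head.

The prediction vocabulary is the deepest-term antichain of sufficiently
frequent BP terms after true-path (is_a) propagation. Evaluation covers
term-centric F1 / MCC / AUPRC medians and protein-centric Fmax
(threshold sweep; averaged precision over predicted proteins, recall over
all) and F_τ, with Wilcoxon / Friedman+Holm significance tests, hold-out,
temporal, and homolog-removal splits, and Naive (annotation frequency)
and PPI-homolog (partner-homolog transfer) baselines. A synthetic module
generates community-structured benchmarks with planted
guilt-by-association signal in exactly the file formats the pipeline
reads.

## Worked example

```python
import string2go as s2

# synthetic benchmark: 300 proteins, 3 communities, noisy annotations
spec = s2.SyntheticSpec()
net, assign = s2.simulate_network(spec)
dag, ann, _ = s2.simulate_ontology_annotations(spec, assign)
vocab = s2.select_term_vocabulary(ann, dag, min_count=30)
split = s2.make_holdout_split(ann, min_terms=1, holdout_size=60, seed=0)

result = s2.run_study(
    net, dag, ann, vocab, split.train, split.holdout,
    heads=("svm", "raw-svm", "naive"),
    embedding_method="node2vec", embedding_params={"d": 32},
    dmnn_cfg=s2.DMNNConfig(hidden_dim=64, seed=0), seed=0)

for head, rep in result.reports.items():
    print(f"{head:8s} median F1 {rep.median_f1:.3f}  "
          f"Fmax {rep.fmax:.3f} at tau* {rep.tau_star:.2f}")
```

Output:

```
svm      median F1 0.884  Fmax 0.908 at tau* 0.47
raw-svm  median F1 0.884  Fmax 0.908 at tau* 0.67
naive    median F1 0.000  Fmax 0.497 at tau* 0.31
```

`svm` is the full method (functional representation + per-term SVMs),
`raw-svm` feeds the raw embedding to the same SVM stage, and `naive`
scores every protein with each term's training frequency. Median F1 is
the median over the six vocabulary terms of hold-out F1 at a 0.5
posterior threshold; Fmax is the best threshold-averaged protein-centric
F-measure, attained at τ\*. The functional representation matches the raw
embedding here (both separate the planted communities nearly perfectly)
while the frequency baseline predicts nothing at the 0.5 threshold —
its per-term scores sit near the ~1/3 annotation frequency.

The same flow is available from the shell:

```sh
string2go simulate --outdir fixtures
string2go run --network fixtures/network.txt --obo fixtures/ontology.obo \
    --annotations fixtures/annotations.tsv --min-count 30 --head svm
```

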