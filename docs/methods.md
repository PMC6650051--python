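# Methods

## The model

`string2go` predicts Gene Ontology biological-process (BP) annotations for
proteins from a weighted protein–protein interaction (PPI) network, under
the guilt-by-association premise: interacting proteins tend to share
function. The method has three stages.

**Stage 1 — network embedding.** Two families are implemented.

*Diffusion-state embedding* (`MashupEmbedding`): for every node *i* the
random-walk-with-restart (RWR) stationary distribution *s\_i* solves

    s_i = r·e_i + (1 − r)·Pᵀ·s_i,

where *P* is the row-normalized weighted adjacency and *r* the restart
probability (default 0.5). Stacking the *s\_i* gives the diffusion-state
matrix *S* = *r*(I − (1 − r)P)⁻¹; a truncated SVD *S* ≈ *U\_d* Σ\_d *V\_d*ᵀ
yields the embedding *U\_d*·√Σ\_d (default *d* = 800, clamped to the node
count on small networks). Networks up to 2000 nodes use the exact dense
solve; larger ones use power iteration to an L1 residual below 1e−8.
Isolated nodes get the indicator diffusion state (the limit of the
defining equation). An optional log-transform log(S + 1/n) is off by
default.

*Biased-walk embedding* (`Node2VecEmbedding`): second-order random walks
of length 10 with return parameter *p* = 1 and in-out parameter *q* = 2
(biasing the walk toward the source neighborhood), 10 walks per node, on
the weighted graph. A skip-gram model with 5 negative samples per pair
(noise distribution ∝ unigram^0.75, window 5, 5 epochs) embeds co-visited
nodes nearby. Typical dimensions are 32–512; the desk-scale benchmark
uses 32.

**Stage 2 — functional representation.** A deep maxout neural network maps
embeddings to sigmoid probabilities over the term vocabulary. Each of the
three hidden blocks computes batch-norm → k = 3 parallel affine maps →
elementwise max → dropout (rate 0.5, training only); the output layer is
affine → sigmoid with one unit per vocabulary term. Training minimizes
binary cross-entropy (mean over samples, summed over terms) with AdaGrad,
learning rate 0.05, batches of 100, 150 epochs, Glorot-uniform
initialization, all seeded. The *functional representation* is the
third block's post-maxout activations taken in inference mode (dropout
off, batch-norm on running statistics), so it is deterministic for a fixed
trained model. Hidden width is selected from {300, 500, 700, 1000} by
k-fold CV: the median-over-terms F1 at threshold 0.5 is rounded to two
decimals and the smallest width attaining the maximum wins.

**Stage 3 — per-term classifiers.** One RBF-kernel SVM per vocabulary
term. Positives are training proteins annotated with the term *or any
is_a descendant*; (C, γ) come from a grid search (defaults C ∈ 2^{−5..9},
γ ∈ 2^{−11..3}, odd exponents) maximizing mean F1 under stratified
k-fold CV (k = 10, reduced to the positive count, minimum 2); ties break
toward smaller C then smaller γ. A logistic sigmoid fitted on
*out-of-fold* decision values (Platt-style, avoiding optimistic
calibration) maps margins to posteriors. The network's own sigmoid output
layer is an alternative head that skips stage 3.

**Baselines.** *Naive*: every protein scores each term with its training
annotation frequency. *PPI-homolog*: for target *p*, collect annotated
training proteins homologous (E ≤ threshold, default 1e−2) to any PPI
partner of *p*; the score for term *t* is the fraction of that set
annotated with *t*.

## Vocabulary and splits

Annotations with experimental evidence codes (EXP, IDA, IPI, IMP, IGI,
IEP) are propagated over is_a (true-path rule). The prediction vocabulary
keeps terms annotating at least `min_count` proteins (default 100;
30 on the 300-protein synthetic benchmark, keeping leaf frequencies near
100 proteins per term in proportion) and then removes any candidate with a
candidate descendant — the deepest-term antichain, ordered
lexicographically. Note that raising `min_count` can move the vocabulary
*up* the DAG (a deep term dropping below threshold exposes its ancestor);
the tests assert exactly this behavior.

Hold-out proteins are sampled uniformly (seeded) from well-annotated
entries; per-branch minimum annotation counts (e.g. ≥28/5/14 BP/MF/CC
terms) are supported through `branch_counts`. Temporal validation selects
proteins with no vocabulary annotation at the training snapshot and at
least one at a later snapshot. Homolog removal consumes a precomputed hit
table (BLAST outfmt-6 compatible) through `HomologyOracle` and drops
evaluation proteins with any training hit at E ≤ threshold; a larger
threshold removes more proteins.

## Evaluation

Term-centric: per-term precision, recall, F1 and MCC at a 0.5 posterior
threshold, and AUPRC by step interpolation (ties form a single
threshold); summaries use the lower median. Zero denominators yield 0 for
precision/recall/F1/MCC; AUPRC is undefined without positives and such
terms are excluded from medians with a warning.

Protein-centric: for each τ on the grid 0.01…1.00 (step 0.01),
per-protein precision of the τ-thresholded prediction set is averaged
over the *m\_τ* proteins with at least one prediction ≥ τ, and per-protein
recall over all *n* proteins; Fmax is the maximum harmonic mean and τ\*
the **largest** maximizing threshold (the most conservative prediction
set). F\_τ re-evaluates the same averaged F at a τ carried over from
another evaluation set, so F\_τ(τ\*) = Fmax on the originating set by
construction.

Method comparisons use the two-tailed Wilcoxon signed-rank test
(zero differences dropped; exact null for n ≤ 25) for pairs, and the
Friedman test with Holm-corrected pairwise post-hocs for three or more
methods, at α = 0.05.

The class-separation analysis min-max standardizes each representation
dimension to [0, 1] over the analyzed proteins (constant dimensions map
to 0), measures the Euclidean distance between annotated/not-annotated
class centroids per term, and reports the Pearson correlation of those
distances with per-term F1.

## Synthetic benchmark

`SyntheticSpec` defaults define the study conditions: 300 proteins in 3
equal communities; planted-partition edges with p\_in = 0.3,
p\_out = 0.02; edge weights 0.8 (within) / 0.3 (between) plus
N(0, 0.05) noise clipped to [0.01, 1]; a depth-3 chain DAG with one root
and 2 leaf terms per community; each protein carries each of its
community's leaves with probability 0.9 and each foreign leaf with
probability 0.05; homology tables designate a configurable fraction of
evaluation proteins as training homologs with log-uniform E-values in
[1e−10, 1e−1]. These sizes keep the full pipeline (embedding → maxout
training → per-term SVM grid search → evaluation) under a minute on one
CPU while leaving enough annotation noise that the classifiers are not
trivially perfect.

What the generator does *not* emulate: scale-free/hub-dominated PPI
topology, realistic GO DAG shape (tens of thousands of terms, multiple
parents everywhere), evidence-code heterogeneity, and sequence-level
homology (hit tables are simulated directly since only the oracle
interface is consumed). Passing tests therefore demonstrate the
machinery's correctness and the relative ordering of methods under clean
guilt-by-association signal, not absolute performance on real corpora.

## Numerical choices

- RWR: exact solve for ≤ 2000 nodes, else power iteration (tol 1e−8,
  max 10 000 iterations, convergence error with final residual).
- SVD sign indeterminacy fixed by the sign of each column's
  largest-magnitude entry, making embeddings reproducible.
- Skip-gram uses mean-gradient minibatch SGD (batches of 1024, learning
  rate 2.5): summed batched updates diverge when the same node index
  recurs many times within a batch, as happens on small vocabularies.
- The maxout network's loss is binary cross-entropy (the standard pairing
  with a sigmoid multi-label output; no alternative is implied by the
  architecture) and the decision threshold for model-selection F1 is 0.5.
- Batch-norm uses momentum 0.9 running statistics and ε = 1e−5; the
  representation is defined in inference mode so it is deterministic.
- Grid-search ties break toward the simpler model (smaller C, then
  smaller γ); duplicate network edges collapse to the maximum weight
  (symmetric and idempotent).
- Degenerate inputs: isolated nodes embed via indicator diffusion states
  and single-node walks; terms with no positives are skipped and scored
  0; empty vocabularies and empty hold-outs are warnings, not errors.

## Known limitations

- The skip-gram and maxout implementations are plain NumPy: correct and
  reproducible, but not performant beyond ~10⁴ nodes; the RWR dense solve
  holds the full n × n diffusion matrix in memory.
- Platt calibration uses a near-unregularized logistic fit on out-of-fold
  decision values; with very few positives the posterior scale is noisy
  (ranking is always preserved).
- Only is_a edges propagate; part_of/regulates semantics are out of
  scope, as are semantic-similarity metrics (S-min) and hierarchical
  consistency post-processing.
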