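# Methods

## Model

The classifier stack couples a fixed, biologically structured feature map
with a learned dense head.

**Hallmark networks.** Inputs are a GMT file of H hallmark gene sets, a
directed gene–gene interaction edge list (TSV), a genes × samples
expression matrix on the log2(TPM+1) scale, and a sample table with
clinical diagnoses and hierarchical subtype labels. The gene universe is
the union of the hallmark sets intersected with the expressed genes, in
expression-matrix order; every downstream matrix indexes rows by it. Each
hallmark's network keeps an undirected edge {i, j} iff either direction
appears in the edge list and both genes belong to that hallmark's set;
genes outside the set stay as isolated nodes so all H adjacency matrices
share one dimension. Restricting edges to within-set pairs is a
configurable choice (`restrict_to_set=False` gives the plain undirected
projection); cross-set edges are excluded by default because each
hallmark's operator is meant to propagate information inside that
hallmark's functional context. Gene symbols are matched case-insensitively
after whitespace trimming; no alias resolution is attempted.

**Embedding.** The message-passing operator per hallmark is
Ā = I + D^(−1/2) A D^(−1/2). D^(−1/2) is undefined at degree 0; we set
those entries to 0, so an isolated gene's operator row is an identity row
and its embedded feature is exactly its own expression (the residual
connection). This is the only convention consistent with both the operator
form and the requirement that neighborless genes fall back to their raw
expression; it is asserted exactly (not to tolerance) in the tests. The
default embedding uses one aggregation layer, identity weights and ReLU;
since log2(TPM+1) input and the operator are non-negative, ReLU is a no-op
and the default slice equals Ā·X exactly, which is what the dense-oracle
tests exploit. Multiple layers and scalar/dense weight matrices are
config options (`EmbeddingSpec`); non-identity weights are applied as
fixed transforms, not trained, because the canonical architecture learns
only in the dense head. The tensor flattens gene-major, hallmark-minor
(feature g·H + h) so attributions map back to (gene, hallmark) pairs
unambiguously.

## Label cleaning

Rules run in a fixed order: (1) optional manual-corrections file
(sample id → replacement label), (2) TRUE/FALSE grouping, (3) FALSE
correction, (4) small-diagnosis-group removal, (5) singleton-label
demotion. Grouping treats "alignment with the diagnosis" as
case-insensitive substring containment of configured tokens: the
diagnosis's primary token must appear in tier 1 and its subtype token in
every deeper tier. Containment (rather than exact token equality) is the
weakest reading that makes the melanoma example work, and is noted as a
choice. A record carrying more than one alternative label path is FALSE by
construction, and if its paths disagree at tier 1 all labels are deleted
(only the diagnosis is kept). FALSE correction replaces tier 1 with the
diagnosis-derived primary label and drops deeper tiers, logging each
change to a JSONL provenance stream; the original path is retained
separately because deep-tier validation needs it. Demotion of
single-sample labels truncates the sample to its (already concordant)
tier-1 label and repeats to a fixed point, since removing one sample can
orphan another label.

## Training protocol

Per tier level k, the training set is every TRUE sample whose label depth
is ≥ k, with the tier-k string as target. The head is a dense softmax MLP
— depth 3 (512 → 256 → C), 2 (256 → C) or 1 (C) — on the flattened
tensor; baselines swap the input (raw expression for the MLP baseline) or
prepend ten 1×1-convolution kernels with 'same' padding (CNN baseline).
Optimization is mini-batch Adam, learning rate 1e-3, batch 200, at most
200 epochs, categorical cross-entropy. Features are standardized per
feature on the training split (the scaler is part of the saved model);
without this the fixed learning rate is unstable on raw-scale inputs, and
it is the standard conditioning step for expression classifiers. Dense
layers use Glorot-uniform initialization.

Early stopping monitors the full-training-set loss evaluated after each
epoch and stops after `patience = 5` consecutive epochs without a decline
of the best loss by more than `min_delta = 1e-4`. The epoch-end
(rather than mid-epoch running) loss makes the monitored sequence
well-defined; `min_delta` stops training from grinding through
float-precision noise once the loss has effectively converged. Monitoring
a validation split instead is a config choice, off by default because the
protocol's stated monitored quantity is the cost function itself.

Cross-validation is stratified k-fold (default k = 5) repeated
(default 5 times) with derived seeds; fold metrics are summarized as
mean ± SD and the fold model with the highest balanced accuracy is the
best model. The separate 60/40 stratified split utility enforces per-label
proportions within one sample. All stochastic steps take explicit seeds;
single-threaded runs are bit-reproducible, which the suite asserts.

## Evaluation

Per-classifier metrics are computed with scikit-learn: accuracy, balanced
accuracy (mean per-class recall — verified against a brute-force formula
on random confusion matrices), weighted F1, micro and macro precision /
recall / F1, and macro AUROC / AUPRC via one-vs-rest decomposition.
A class absent from the evaluated truth has no defined one-vs-rest curve
and is excluded from the macro average with a warning rather than imputed
0.5, which would bias small folds.

The three hierarchical validation metrics are defined minimally and
consistently with their required ordering: separate accuracy scores tier k
alone over samples whose reference defines tier k; combined accuracy at k
requires the whole predicted prefix 1..k to match; sample-level accuracy
requires every defined reference tier to match. Hence combined ≤ separate
per level and sample-level ≤ combined at maximal depth, and with
independent per-level errors combined accuracy follows the product of the
separate accuracies (checked by simulation at n = 5000). For FALSE-group
validation the tier-1 reference is the corrected diagnosis-derived label
and deeper tiers come from the original pre-correction path; samples whose
labels were deleted contribute only at tier 1.

## Interpretation

The attribution backend is a permutation-sampling Shapley estimator:
features are inserted in random order into a background sample redrawn per
permutation, and marginal changes of the class probabilities are averaged
over permutations. For a linear model each permutation is exact given its
background, so the estimator is validated against the closed form
φ_i = w_i (x_i − E[x_i]). Scores are summarized as the mean absolute value
over explained samples and output classes, per (gene, hallmark) feature;
genes outside a hallmark's set still own that slice's feature and are
counted toward it — a documented consequence of the dense tensor layout.
Gene-level scores (summed over hallmark copies) are normalized to total 1
per classifier before ranking, ties breaking alphabetically. Hallmark
contributions divide the summed per-hallmark attribution by the hallmark's
gene count within the universe and min-max normalize across hallmarks;
all-equal raw values map to all-zero by convention. Pairwise top-k overlap
of gene rankings (default k = 2000) and Pearson correlation of selected
genes complete the reporting; the overlap statistic is validated against
its hypergeometric expectation k/N for independent rankings.

## Synthetic cohorts

The generator emulates the four inputs with planted structure. Defaults —
the reference study conditions for all end-to-end tests — are: 200
universe genes plus 20 expression-only genes, 10 hallmarks built from a
random partition with 25% overlap added, Erdős–Rényi interactions at edge
density 0.05 (average within-hallmark degree ≈ 1.2, mirroring the sparse
curated-interaction regime at this scale), a single-tier label tree with
3 primary classes × 100 samples, 20 informative genes per class with mean
shift Δ = 2, Gaussian noise SD 1 on a lognormal(1, 0.5) per-gene baseline
rectified at 0 (keeping values on the non-negative log2(TPM+1) scale),
10% deliberately discordant samples, seed 7. Discordant samples keep the
expression of their true class but carry another class's token in their
label (tier 2 for deeper trees, tier 1 for flat ones), so the grouping
logic must flag exactly them; an optional planted singleton label
exercises the demotion rule. The manifest records ground truth
(group assignment, per-level counts, per-hallmark edge counts, informative
genes) computed directly from the planted design, independent of the
pipeline code it is used to check. Same seed → byte-identical files.

What the generator does not emulate: count noise (negative binomial),
library-size and batch effects, correlated co-expression modules, realistic
hallmark set sizes (hundreds–thousands of genes), or label trees deeper
than eight tiers. Passing tests therefore demonstrate mechanical and
statistical correctness of the pipeline, not clinical performance on real
cohorts.

## Problem sizes and numerical choices

The suite and the acceptance script run on cohorts of 100–300 samples with
30–240 genes, chosen so the planted effects are comfortably detectable at
those n. Dense-oracle comparisons use graphs of ≤ 20 nodes at tolerance
1e-8 (observed agreement is at machine precision); metric brute-force
checks use 200 random confusion matrices at 1e-9; Monte-Carlo assertions
(product law, overlap expectation, Shapley sampling error) use tolerances
of ~3 standard errors at their stated n. Probabilities are clipped at
1e-12 before logs; softmax is max-shifted. Argmax ties resolve to the
lowest vocabulary index. The dominant-gene attribution check uses
fixtures with a single informative gene per class and no edges, because
with edges the planted signal legitimately diffuses to network neighbors
and "the planted gene ranks first" is no longer the correct expectation.

## Known limitations

* The embedding's weight matrices are fixed (identity by default), not
  trained jointly with the head; the canonical architecture needs no
  gradients through the graph operator, so none are implemented.
* Kernel-style regression Shapley is not provided; the permutation
  estimator is O(features × permutations) forward passes per sample and is
  sized for fixture-scale models.
* Hierarchical consistency is not enforced at prediction time: per-tier
  classifiers are independent, so a predicted tier-2 label need not be a
  child of the predicted tier-1 label (combined accuracy measures exactly
  this).
* Gene-symbol handling is exact-match only; real cohorts need upstream
  identifier harmonization.
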