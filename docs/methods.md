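# Methods

## Problem and model

Given a binary microbe–disease association matrix A (N_m × N_d) and four
precomputed similarity matrices per entity side, the package scores every
microbe–disease pair with the probability-like value
Â_ij = σ(Corr(λ_i, λ_j)), where λ_i and λ_j are learned embeddings and σ
is the logistic function.  The model assumes that (a) the similarity
sources are noisy views of one underlying biological relatedness, so a
consensus network is more reliable than any single view; (b) entities that
are similar, or that share association partners, tend to share
associations; and (c) only positive labels are trustworthy — zeros are
unlabeled, not negative.

The pipeline has four stages.

**Similarity fusion.**  Each of the three kernel views per side is
row-normalized with its diagonal pinned at 1/2 (so every row sums to 1 and
no self-similarity dominates), and reduced to a sparse row-stochastic KNN
affinity over the ⌊N/10⌋ strongest neighbors per row (self excluded, ties
broken toward the lower index for determinism).  Cross-diffusion then
updates all views simultaneously — view k is replaced by its affinity
applied on both sides to the average of the *other* views from the
previous sweep — until every view's relative Frobenius change drops below
`fusion_tol`.  After each sweep the views are re-normalized with the same
diagonal-1/2 row normalization.  This renormalization is essential, not
cosmetic: without it the update is a strict contraction and, whenever a
KNN graph is connected, the iterates converge to a constant matrix — the
stopping rule fires, but the "fused" result carries no similarity signal.
The un-renormalized update remains available (`renormalize_views: false`)
and its collapse is pinned by a regression test.  The mean of the
converged views is symmetrized and merged with the functional/semantic
similarity: SM″ = α·SM′ + (1−α)·FS.

**Homogeneous encoder.**  One graph-convolution layer per side on the
fused graph, using the graph itself as the feature matrix:
SM‴ = ReLU(P · SM″ · W) with P = D^(−1/2) SM″ D^(−1/2).  The symmetric
normalization is the standard GCN operator; the variant with a positive
right exponent is available behind `literal_normalization` for
comparison.  No extra self-loops are added here — the fused matrix already
has a dominant diagonal by construction.

**Heterogeneous encoder.**  The bipartite graph G̃ = [[0, A], [Aᵀ, 0]]
gets identity self-loops before normalization so that entities without
any training association retain a defined degree (their embeddings reduce
to transforms of their own features).  Each multi-neighborhood layer
concatenates P̃^i H W_i over neighborhood orders i = 0…k; each W_i maps to
⌊layer_size/(k+1)⌋ columns with the remainder assigned to the order-0
block, keeping layers stackable at a constant width.  A ReLU follows each
layer.  Jumping-knowledge aggregation sums the layer outputs with
coefficients ω_l, trainable by default (initialized uniform at 1/l) and
freezable via `jk_learnable: false` when exact run-to-run reproducibility
of the score matrix matters.

**Decoder and loss.**  Embeddings from the two stages are concatenated
per entity; pairs are scored by the Pearson correlation of the two
vectors through a sigmoid, which confines scores to
(σ(−1), σ(1)) ≈ (0.269, 0.731).  A consequence worth knowing: the
cross-entropy of a positive pair is bounded below by −ln σ(1) ≈ 0.313, so
the training loss cannot approach zero even on a perfectly ranked
training set; ranking, not calibration, is what the decoder optimizes.
The loss is the *sum* (not mean) of the binary cross-entropy over the
selected positive and negative pairs; a mean-reduction switch exists
because the choice rescales the effective learning rate.  Optimization is
Adam with decoupled weight decay, a fixed epoch budget and no early
stopping.

## Training without a deep-learning framework

The trainable graph (a few dozen dense operations) runs on a compact
reverse-mode autodiff engine written on NumPy (`sgjmda._autodiff`), with
Glorot-uniform initialization driven by the run seed and a hand-written
AdamW step.  Gradient correctness is established by central
finite-difference checks in the test suite, for each primitive and for
the composed model under every ablation variant.  All computation is
float64 and single-threaded, which makes the full fit→predict path
bitwise reproducible for a fixed seed.

## Tunable parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.28 | convex weight of the diffused consensus vs FS/DS in the merge (dimensionless, [0,1]) |
| `knn_divisor` | 10 | neighbors per row = ⌊N/divisor⌋, minimum 1 |
| `fusion_tol` | 1e-6 | relative Frobenius stopping tolerance of cross-diffusion |
| `layer_size` | 128 | embedding dimension after every encoder stage |
| `n_hetero_layers` | 2 | multi-neighborhood GCN depth |
| `k_neighborhood` | 4 | maximum propagation order (blocks 0…k) |
| `lr`, `wd` | 1e-3, 1e-5 | Adam learning rate and decoupled weight decay |
| `epochs` | 2000 | fixed training budget (no early stopping) |
| `neg_strategy` | random | `random` or `kmeans` negative sampling |
| `n_neg_clusters` | 10 | clusters for the k-means strategy |
| `threshold` | 0.5 | score cutoff for accuracy/precision/recall/F1 |

The first seven defaults are the method's reference operating point; the
threshold of 0.5 is the conventional cut and sits midway inside the
attainable score interval.  The k-means cluster count is a package
default — the convention this strategy imitates does not publish one.

## Negative sampling and evaluation protocol

Training negatives are drawn 1:1 with the positives, once per fit (not
per epoch), either uniformly from the unlabeled pairs or by clustering
unlabeled pairs on concatenated entity features and spreading the quota
proportionally across clusters (largest-remainder rounding, empty-cluster
quota redistributed).  During cross-validation the candidate pool is the
unlabeled set of the *original* matrix: a held-out positive is a known
association whose label is hidden from training, not a legitimate
negative, so it can never be trained as a zero.  Test negatives are
sampled 1:1 with the fold's test positives, disjoint from the training
negatives and from every known positive.  Folds partition the shuffled
positives with sizes differing by at most one.  AUC uses midrank tie
handling; AUPR is the step-interpolated precision–recall area.

One caveat is inherited from the data-generation convention rather than
fixed here: the input similarity matrices (e.g. interaction-profile
kernels) are derived upstream from the full association matrix, so
cross-validation over a fixed similarity input can carry fold information
exactly as the published protocol does.

## Synthetic benchmark

`sgjmda.synthetic` draws microbe and disease latent factors from a
spherical Gaussian, labels the top `association_density` fraction of
latent inner products as positives (thresholding rather than Bernoulli
sampling, so the positive count — and hence fold arithmetic — is exact),
and builds every similarity view as the cosine similarity of the latents
plus independent symmetric noise, clipped to [0,1] with unit diagonal.
The default instance used throughout the tests and the acceptance script
is 120 microbes × 20 diseases, rank 4, density 0.05 (120 positives),
noise 0.1, with training runs of 200 epochs — sizes chosen so a full
cross-validation completes in seconds to minutes on one CPU.

What the generator does and does not emulate: it reproduces the shared
latent structure, the sparsity and the multi-view redundancy of the real
benchmark, but not ontology-driven block structure in the semantic
similarity, heavy-tailed degree distributions, or annotation errors in
the labels.  Passing recovery tests on it demonstrates that the pipeline
extracts planted low-rank structure from noisy views; it does not certify
performance on curated biomedical data.

## Known limitations

* **Edge density and the heterogeneous stage.**  At the synthetic
  benchmark's scale (~0.8 training edges per microbe, versus roughly 3
  per entity in the curated benchmark the method targets) the
  multi-neighborhood stage has little neighborhood signal to propagate
  and can instead memorize the training edges; longer training lowers
  held-out ranking quality, and the simpler no-heterogeneous and
  inner-product-decoder variants can match or exceed the full model.  The
  ablation CLI (`sgjmda ablate`) computes this comparison directly.  On
  dense association matrices the relative ordering is expected to
  reverse, which is the regime the full architecture is designed for.
* The bounded score range means emitted values are not calibrated
  probabilities.
* The fusion stage assumes every entity has at least one positive
  off-diagonal similarity in each view; fully isolated rows are an error
  by default (`uniform_row_fallback` substitutes a uniform row).
* No GPU path and no minibatching: the implementation targets matrices of
  a few thousand entities at most.
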