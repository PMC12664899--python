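# Methods

This note documents the models, the numerical choices behind them, what
the synthetic benchmark does and does not emulate, and the limitations a
user should know about.

## Problem setting

Given an annotated reference count matrix `SI` (n_ref cells × d genes,
one cell-type label per cell) and a spatial count matrix `TI` (n cells ×
d genes, one 2-D coordinate per cell), produce a label and a probability
vector over the reference's C types for every spatial cell. Two obstacles
shape the design: a systematic batch effect between the modalities
(different chemistry, capture efficiency, gene panels), and the fact that
per-cell ST measurements are noisy enough that a cell's neighborhood
carries real information about its identity.

## Stage 1 — conditional count VAE

Both datasets, restricted to their shared genes, are modeled by a single
variational autoencoder with the modality as a conditioning covariate.

* **Likelihood.** Negative binomial per gene: the mean is the observed
  library size times a softmax-decoded gene proportion, with a free
  per-gene inverse-dispersion. This is the standard count model for
  integration of this kind; raw counts go in, no prior normalization.
* **Architecture.** Encoder `log1p(counts) ⊕ batch-onehot → 128 (ReLU) →
  (μ, log σ²)` with a 30-dimensional latent; decoder `z ⊕ batch-onehot →
  128 → 128 → softmax(d)` (two hidden layers). Latent 30 / hidden 128 /
  two decoder layers are the published configuration of the method.
* **Embedding.** The posterior mean μ, so that encoding is deterministic
  and repeated calls are bit-identical for fixed weights.
* **Training.** Minibatch Adam (batch 256, lr 1e-3), seeded; up to 400
  epochs with early stopping once the epoch-mean negative ELBO improves
  by less than 0.1% over 15 consecutive epochs.
* **KL warm-up.** The KL term is annealed linearly over the first 50
  epochs. Without it the model reaches a local optimum in which the
  decoder explains the data through its bias alone and the latent
  collapses to the prior (observed directly: latent standard deviations
  ~1e-3 and chance-level downstream classification); with it the latent
  carries the type structure. Warm-up of this kind is the default in the
  reference implementations of conditional count VAEs.
* **One joint model.** A single VAE on the concatenated datasets (rather
  than one per modality) is the only construction in which both
  embeddings live in the same space with the same dimensionality, which
  downstream stages require.
* **Ablation.** `skip_vae=True` replaces stage 1 with joint log1p-CP10K
  PCA — useful for quantifying what integration contributes.

## Stage 2 — boosted-tree teacher

An XGBoost ensemble on the annotated reference embedding `SSI` provides
the transfer signal.

* **Probabilities, not hard labels.** The softprob objective yields the
  row-stochastic teacher distribution D over types for each spatial cell;
  a hard-label teacher could not define the distillation cross-entropy.
* **Regularization.** DART booster with tree-drop rate 0.1 — dropout at
  the only level at which it exists in a tree ensemble.
* **Split finding.** `tree_method="exact"`. With histogram-based split
  finding the candidate cuts are quantiles of the training data, so
  inside the empty margin between two well-separated classes the cut
  lands at one class's edge; borderline held-out cells then fall on the
  wrong side of the same cut in many trees and are confidently
  misclassified. Exact midpoint splits avoid this.
* **Round selection.** Stratified `k_n_fold` (default 5) cross-validation
  with early stopping picks the boosting-round count; the final ensemble
  is refit on all reference cells with that count, and the cross-validated
  accuracy is logged. CV scoring predicts with the full early-stopped
  booster because DART tree weights are not truncation-consistent.
* A multinomial-logistic teacher (`teacher_backend="linear"`,
  D = softmax(TTI·W + b)) is available as an alternative backend.
* Classes with fewer than `k_n_fold` members are rejected with advice to
  merge or drop them. Ties in argmax resolve to the lowest class index.

## Stage 3 — spatial graph

Each spatial cell connects to its k = 30 nearest Euclidean neighbors;
edge weights are `W(u,v) = exp(−d(u,v)²/2θ²)`.

* **θ = "auto"** resolves to the median k-NN distance, making the kernel
  scale-free across platforms whose coordinates are in different units.
  Scaling all coordinates and θ by the same factor leaves the graph
  unchanged.
* **Symmetrization** by elementwise maximum of the directed k-NN matrix
  and its transpose, preserving every selected edge's kernel value.
* The adjacency A keeps a zero diagonal; self-loops are introduced only
  in the symmetrically normalized matrix `Ã = D̂^(−1/2)(A+I)D̂^(−1/2)`
  used by the convolutions. Duplicate coordinates are legal (weight-1
  edges); k ≥ n−1 degrades to the complete graph with a warning.

## Stages 4–5 — dual autoencoder / graph autoencoder with distillation

* **AE.** Encoder FC(d→128)→BN→ELU→Dropout, FC(128→30)→BN→ELU→Dropout
  gives X; decoder FC(30→128)→BN→ELU→Dropout then a plain linear map back
  to d (no BN on the final layer, following the printed architecture).
  Dropout p = 0.2; BN uses batch statistics in training and running
  statistics (momentum 0.1) at inference.
* **GAE.** S = Ã·(Dropout(ReLU(Ã·(X·W₁)))·W₂), convolution weights
  30×30 without biases. Fusion Z = X + S; the AE latent width equals the
  VAE latent width so the sum is well-typed.
* **Losses.** `L_AE` = mean squared error over all n·d entries.
  `L_SSL = −(1/nc) Σ D log P` — note the 1/(n·c) normalization, smaller
  than standard cross-entropy by the class count; the weight `w_cls`
  absorbs the difference, which is one reason its default (20) is large.
  `L_GAE` is binary cross-entropy between the adjacency and
  `A' = σ(ZZᵀ)`, with two numerical choices:
  * **Binarized, class-balanced target** (default): edges plus the
    diagonal are the positive class, everything else negative, and the
    loss averages the mean positive BCE and the mean negative BCE so
    that sparsity (~n·k positives among n² entries) does not drown the
    edges. Kernel-weighted targets in [0,1] remain available behind
    `binarize_adjacency=False`.
  * **Subsampling above 2,000 cells**: the full n² sum is replaced by all
    positive entries plus an equal number of uniformly sampled negative
    pairs, resampled each epoch (seeded). The estimator is unbiased for
    the balanced loss; the test suite verifies this against the exact
    double sum on small graphs (100 resamples, 3 standard errors).
* **Training.** Full-batch Adam (lr 1e-3), 200 epochs, weights
  (w_cls, w_dae, w_gae) = (20, 1, 1). The teacher distribution is frozen
  throughout (it is an input, not a co-trained module). A non-finite loss
  aborts with the epoch and learning rate in the message. With a fixed
  seed and single-threaded execution two runs produce identical
  parameters; loss trajectories are recorded per epoch on the state.
* **Prediction.** Eval mode (dropout off, BN running statistics);
  labels are the row-argmax of P = softmax(Z·W_student + b_student),
  ties to the lowest class index.

## Synthetic benchmark

`make_synthetic_reference` draws gamma-Poisson (negative binomial,
inverse-dispersion 2.0) counts for four types plus background over 500
genes; each type overexpresses its own disjoint block of 25 signature
genes 4-fold; library sizes are gamma with mean 2,000. The background
type has a flat profile and is the explicit label "background", included
in accuracy denominators. `make_pseudo_st` samples spatial expression
rows with replacement from reference cells of the region's type:
hierarchical layout = four unit-height rows on [0,1]×[0,4] with 1,000
cells per type plus 400 uniformly scattered background cells; block
layout = four 100×100 squares in a 200×200 field with 300 background
cells. A per-gene lognormal factor (sd 0.3) multiplies the spatial counts
so the modalities differ by a real batch effect.

What this does **not** emulate: platform-specific noise (segmentation
errors, probe panels, spot mixing), spatially smooth expression gradients
within a type, rare types, or label noise in the reference. Passing the
recovery tests therefore demonstrates that the pipeline's machinery is
sound and that spatial smoothing corrects teacher errors — not that the
published accuracies on real tissues are reproduced; those depend on
external datasets.

## Problem sizes in tests and the acceptance script

The acceptance script runs the two full benchmark pairs (4,400 and 4,300
spatial cells, 500 genes, 5,000 reference cells) end to end; unit and
property tests use down-scaled instances (tens to hundreds of cells) of
the same generators. The neighbor-smoothing experiment injects 10%
label noise into a one-hot teacher on a 850-cell hierarchical pair and
trains the annotator for 60 epochs per seed — enough for the smoothing
effect, which appears within the first few dozen epochs, while keeping
five seeded repetitions cheap.

## Known limitations

* Full-batch GAE training holds the n×30 latent and the sampled edge set
  in memory; beyond ~10⁵ cells minibatched neighbor sampling would be
  needed (out of scope here).
* The method presumes spatial contiguity of types; highly dispersed
  populations gain nothing (and can lose) from neighborhood smoothing —
  visible in the simulations as background cells absorbed into their
  surrounding region.
* 2-D coordinates only; 3-D is a documented extension point of the graph
  module.
* Gene matching is exact string identity (optional case-folding); no
  ortholog or alias resolution.
* The teacher is uncalibrated (no temperature scaling); `w_cls` partially
  compensates for overconfident teachers.
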