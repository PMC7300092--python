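# Methods

This note documents the models implemented in `scdiffvae`, the conventions
and numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions made where the design was
genuinely open.

## Data model and preprocessing

Inputs are cells × genes matrices of log-normalised expression (CSV/TSV with
gene-name header and cell-id index, or MatrixMarket with `genes.txt` /
`cells.txt` sidecars; orientation is auto-detected from the sidecar lengths
and can be forced). A `--log1p` option exists for raw-count inputs; by
default no further log transform is applied.

`preprocess.minmax_scale` rescales **each gene** across cells to `[0, 1]`
(`(x − min)/(max − min)`), so that the decoder's logistic output can model
every gene as a Bernoulli variable. Scaling per gene (rather than globally)
keeps every gene on a comparable scale regardless of its dynamic range; the
per-gene minima and ranges are retained for exact inversion. Constant genes
map to 0 and are flagged in the log — they are kept, not dropped, so that
gene indices stay aligned with the decoder-weight analysis.

## DiffVAE

Architecture (defaults, used for all hematopoietic-scale experiments):
encoder `k → h2 → h1` with ReLU and batch normalisation after each hidden
affine transform (before the ReLU), two parallel heads `h1 → m` for μ and
log σ²; decoder `m → h1 → h2 → k` with ReLU hidden layers and logistic
output. Defaults: `h1 = 256`, `h2 = 2·h1 = 512`, `m = 50`, Adam with
learning rate 0.001, batch size 128, 100 epochs.

Objective (minimised):

    BernoulliNLL(x, x′) + mmd_weight · MMD²(z_batch, prior_batch)

- The reconstruction term is the continuous-label binary cross-entropy,
  summed over genes and averaged over the batch. Decoder outputs are clamped
  to `[1e-7, 1 − 1e-7]` inside the NLL; the gradient uses the fused
  logistic/cross-entropy form and needs no clamp.
- The MMD term is the biased (V-statistic) squared maximum mean discrepancy
  between the reparameterised minibatch codes and a fresh standard-normal
  batch of the same size, drawn per step. The V-statistic keeps the estimate
  nonnegative. The kernel is a sum of RBF kernels
  `exp(−‖a−b‖²/(2h²))` with bandwidths `h = sqrt(m/2)·c`,
  `c ∈ {0.1, 0.5, 1, 2, 10}` — `sqrt(m/2)` is the median-heuristic order of
  magnitude for distances between m-dimensional standard-normal samples, and
  the multi-bandwidth family avoids committing to a single length scale.
  `mmd_weight` defaults to 1.0 (the objective as printed, with no extra
  coefficient); both the weight and the bandwidth list are configurable.

**Encoder heads.** The published equations apply ReLU to both the μ and the
log σ² head, which constrains μ ≥ 0 and σ ≥ 1. This is unusual (the posterior
can never be sharper than the prior) and may be a transcription artifact, but
it is kept as the default (`head_activation="relu"`) for fidelity; a
`"linear"` option provides the conventional unconstrained heads. All
end-to-end results in the test suite are obtained with the default.

**Latent representation.** Downstream analyses use the posterior mean μ per
cell — the maximum-likelihood point of `q(z|x)` — with no sampling. Batch
normalisation runs in inference mode (exponential running statistics,
momentum 0.9, ε = 1e-5) whenever a dataset is encoded, so the latent code of
a cell does not depend on which other cells are encoded with it.

**Determinism.** Weight initialisation (Glorot uniform), epoch shuffling,
reparameterisation draws and prior draws all flow from a single seeded
`numpy.random.Generator`; all state is float64. Two runs with the same seed
produce bit-identical weights, which the test suite asserts for every
training entry point. The final partial minibatch of each epoch is kept.
Non-finite losses abort with a diagnostic rather than continuing silently.

**Hyperparameter selection** trains each grid point on a seeded 80/20 split
and keeps the configuration with the lowest validation loss (reconstruction +
MMD of the validation codes against a seeded prior batch); ties break toward
smaller m, then smaller h1. The published grid is `h1 ∈ {256, 128}`,
`m ∈ {50, 100}`, learning rate `∈ {0.01, 0.001, 0.0001}`, batch size
`∈ {64, 128, 256}`.

The networks are implemented directly on numpy with hand-written backward
passes (`nn.py`: dense, batch norm, ReLU, Adam). This keeps the dependency
footprint small and makes bit-exact seeded reproducibility straightforward;
gradient correctness is verified against central finite differences in the
test suite.

## Baselines

The standard VAE swaps the MMD term for the closed-form Gaussian KL
`½ Σ_d (μ_d² + σ_d² − 1 − ln σ_d²)` and is otherwise identical (same layer
sizes, batch norm, logistic output, Adam, lr 0.001, batch 128). The plain
autoencoder uses the same encoder trunk with a linear bottleneck of width m
and minimises the squared reconstruction error through the same
logistic-output decoder; its latent representation is the bottleneck
activation. PCA centres genes (no re-scaling — the input is already
Min-Max scaled) and returns the top-m scores, with the sign convention that
each component's largest-magnitude loading is positive.

## Cell-type identification

1. **Embedding/clustering.** t-SNE (perplexity 30, seeded) reduces the latent
   means to 2-D; k-means (seeded) or DBSCAN labels cells. DBSCAN noise cells
   carry label −1.
2. **Dimension relevance.** For each latent dimension k, the extreme set
   `D_k = { i : z_k^(i) ≥ μ_k + σ_k or z_k^(i) ≤ μ_k − σ_k }` (boundaries
   inclusive) is computed with the **population** standard deviation (divide
   by N): the statistic describes the full dataset, not a sample. A
   degenerate dimension (σ_k = 0) would literally select every cell, which
   carries no information, so it returns the empty set and is flagged. For
   each cluster C and dimension k, the percentage of `D_k` belonging to C is
   recorded (noise counts as its own cluster, so percentages sum to 100);
   the top dimensions for C are those with the highest percentage,
   descending, ties broken by dimension index. An empty `D_k` scores 0 % for
   every cluster.
3. **Gene weights.** `ω = W⁽⁰⁾·W⁽¹⁾·W⁽²⁾` composes the decoder's weight
   matrices, excluding biases and ReLU/logistic nonlinearities, exactly as
   defined — note this is a *linearisation* of the decoder, equivalent to
   decoding the latent standard basis through the bias-free linear map.
   Per-dimension gene rankings use `|ω_ij|` descending (ties by gene index),
   and the genes common to all of a cluster's selected dimensions are
   reported alongside per-gene dimension counts.
4. **Marker calls.** The package's cluster-level marker list
   (`celltype.cluster_marker_genes`) ranks genes by `Σ_k |ω_kj|` pooled over
   the cluster's selected dimensions. Pooling matters: a disentangled model
   concentrates each cluster in a small number of dimensions, so when a fixed
   number of top dimensions is analysed, the weaker ones contribute weight
   rows still dominated by initialisation noise. Summing pools the signal of
   the informative dimensions while the noise averages out; on the synthetic
   fixture this raises per-cluster marker precision from ~0.2–0.45 (union of
   per-dimension top-3 lists) to 0.7–1.0 across seeds.
5. **Benchmarking.** The ARI benchmark repeats clustering (and the t-SNE
   embedding, where used) with fresh seeds — 50 repeats by default — for
   every (model, m, clusterer, embedding) combination and reports mean ARI in
   a long table plus a pivoted summary. ARI treats DBSCAN noise as one extra
   cluster by default; a `drop` policy removes noise cells instead.

## Cell-state perturbation

A softmax MLP classifier (hidden layers 256/512/256, ReLU; Adam, lr 0.001,
batch 128, 300 epochs; scikit-learn) is trained on the mature cell types
using full gene expression. To convert source (progenitor) cells toward a
target type: encode, shift the target's top relevant dimensions by
`direction · λ · σ_k`, decode, classify. The shift **direction** per
dimension is the sign of (target-cluster mean − dimension mean) — the
extreme-cell rule is two-sided, so the shift must point toward the side of
the dimension mean where the target population actually sits; it can be
overridden. Classification uses the argmax, with no probability threshold.

Gene-level analysis: `Δ = y − x` between the converted reconstruction and the
original expression, ranked by |Δ| (ties by gene index). The minimal gene set
is found by a ranked-prefix scan — substitute the top-g genes of y into x and
find the smallest g the classifier accepts as the target (g = 0 if x already
classifies as the target; g ≤ k always, since the hybrid equals y at g = k).
This is an ordered substitution, not a combinatorial subset search.

Conversions are computational hypotheses about reprogramming, not biological
claims; on synthetic data the conversion fraction increases monotonically in
λ, which is the behaviour the method is designed to exhibit.

## Graph-DiffVAE

The initial graph connects each cell to its most positively
Pearson-correlated peer (ties to the lowest index; cells with no positive
correlation, including zero-variance cells, stay isolated with a warning);
the union of directed picks is symmetrised. Graphs are stored without
self-loops; self-loops are added only for propagation and as the
reconstruction target's diagonal.

Encoder: one shared ReLU GCN layer (512 features) feeding two linear GCN
heads (M = 50) for the per-node Gaussian posterior. Decoder: ReLU GCN (512)
on the concatenation [Z | X], then a ReLU GCN to Z′ (M features) — Z′ is
therefore nonnegative, as the printed architecture implies — and
`Z* = ½(Z′ + Z)`, `Â = sigmoid(Z* Z*ᵀ)`. GCN layers follow
`X′ = τ(D^{-1/2}(A+I)D^{-1/2} X W)` with no bias.

Training is full-graph (no minibatching) Adam, default learning rate 1e-4 for
200 epochs, with one reparameterised sample of Z per epoch; the KL term is
closed-form. The reconstruction term is Bernoulli cross-entropy over the full
dense self-loop-augmented adjacency, averaged per node. Because the
correlation graph is very sparse, the literal unweighted objective is nearly
minimised by predicting no edges at all; the positive class is therefore
up-weighted by `#non-edges / #edges` by default (`edge_pos_weight = 1.0`
restores the literal objective). Predicted links are the non-input pairs with
`Â_ij ≥ 0.5` by default; a top-q mode is provided because fixed thresholds on
imbalanced score matrices are brittle. Input edges are always reported
separately from novel ones.

## Synthetic data

The generator emulates the *statistical structure the methods assume*, on the
log-normalised scale the models consume: `n_clusters` mature populations,
each with `markers_per_cluster` planted marker genes whose mean is
`base_scale + marker_effect` inside the cluster and `base_scale` elsewhere;
all other genes share the cluster-independent mean `base_scale`; additive
Gaussian noise (sd `noise_sd`) truncated at zero; optionally a progenitor
population whose centroid is the average of the mature centroids, giving the
perturbation method a meaningful "between" population. Labels are contiguous
blocks of cell index, so they are a deterministic function of the index; one
seeded RNG stream drives the whole draw. Defaults (500 cells × 200 genes, 4
clusters, 10 markers each, effect 3.0, noise 0.5) give well-separated
populations of the kind the real datasets' curated highly-variable-gene
matrices exhibit.

It deliberately does **not** simulate count-level phenomena — dropout,
library-size variation, negative-binomial dispersion — nor batch effects or
correlated background genes. Passing tests therefore demonstrate that the
implementations are correct and that the pipeline recovers planted structure
under clean conditions; they do not certify performance on real scRNA-seq
noise characteristics.

The within-cluster ground-truth graph (`generate_labeled_graph`) links each
cell to k random same-cluster neighbours and symmetrises, giving the graph
models a target in which every true edge is a same-cluster pair.

## Problem sizes and runtime

End-to-end checks run at the scale the synthetic study conditions define:
cluster/marker recovery on 500 cells × 200 genes with m = 20 and 40 training
epochs (5 t-SNE + k-means repeats); perturbation on the same size with a 20 %
progenitor population and a 100-epoch classifier; link prediction on 100
cells with the full 200-epoch schedule. The complete test suite runs in
about a minute on one CPU; `scripts/acceptance.py` in under a minute.

## Known limitations

- The Bernoulli NLL of fractional targets has a large irreducible entropy
  floor, so reported losses are dominated by a constant; compare losses only
  between runs on the same data.
- With ReLU heads (the default), μ ≥ 0 and σ ≥ 1: the aggregate posterior can
  never match the standard-normal prior exactly, and the MMD term acts only
  as a soft regulariser.
- ω is a linearisation of the decoder; it ignores which hidden units a given
  cell actually activates. Its gene rankings are global per dimension, not
  cell-specific.
- The correlation graph is a proof-of-concept initialisation; any
  biologically motivated edge list can be supplied instead, and predicted
  links inherit the semantics of the input edges.
- Full-graph GCN training is O(N²) in memory via the dense Â and is intended
  for datasets of a few thousand cells, not atlas scale.
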