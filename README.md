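# scdiffvae

Unsupervised modelling of cell differentiation from single-cell RNA-seq
expression data. The package implements **DiffVAE**, an MMD-regularised
(InfoVAE-family) variational autoencoder, together with a pipeline that turns
its latent space into biology: identifying cell-type clusters, reading
cluster marker genes off the decoder weights, converting cell states
in-silico by perturbing the latent code, and predicting cell–cell links with
a graph convolutional variational autoencoder (**Graph-DiffVAE**). A
synthetic-data generator with planted cluster/marker structure makes every
stage testable without downloading real datasets.

It is aimed at computational biologists who want interpretable low-dimensional
representations of scRNA-seq data — in particular, representations whose
individual dimensions can be linked back to cell populations and genes.

## The model

Each cell's log-normalised expression vector `x ∈ R^k` is Min-Max scaled per
gene to `[0, 1]` and modelled as a multivariate Bernoulli. A fully connected
Gaussian encoder (two ReLU hidden layers of `h2 = 2·h1` and `h1` units, batch
normalisation) produces a posterior `q(z|x) = N(μ, diag(σ²))` over an
`m`-dimensional code; a mirrored decoder with logistic output reconstructs
`x′ ∈ (0, 1)^k`. Training minimises

    L = BernoulliNLL(x, x′) + λ · MMD²( q(z), N(0, I) )

where the maximum mean discrepancy is estimated with a biased V-statistic
over a multi-bandwidth RBF kernel family, comparing each minibatch of sampled
codes `z = μ + ε ⊙ σ` with a fresh standard-normal batch. Matching the
*aggregate* posterior to the isotropic prior (instead of the per-sample KL of
a standard VAE) preserves mutual information between cells and codes and
encourages disentangled latent dimensions.

Downstream analyses use `z = μ` and three simple constructions:

- **Extreme-cell sets** `D_k = { i : |z_k^(i) − μ_k| ≥ σ_k }` — the cells at
  least one standard deviation from a dimension's mean. The share of `D_k`
  falling in a cluster ranks which dimensions encode that cluster.
- **Gene-weight matrix** `ω = W⁽⁰⁾·W⁽¹⁾·W⁽²⁾` — the decoder's composed (bias-
  and activation-free) weight matrix; `|ω_ij|` scores the influence of latent
  dimension `i` on gene `j`, yielding cluster marker genes.
- **Latent perturbation** `z′_j = z_j + direction_j · λ · σ_j` on a cluster's
  relevant dimensions — decoding the shifted code and re-classifying it asks
  whether a progenitor cell has been converted into a chosen mature type.

Graph-DiffVAE treats cells as nodes (features = expression), starting from a
graph that joins each cell to its most positively Pearson-correlated peer. A
GCN encoder/decoder pair (`X′ = τ(D^{-1/2}(A+I)D^{-1/2} X W)`) produces
latent node features and a dense edge-probability matrix
`Â = sigmoid(Z* Z*ᵀ)`, trained with edge-weighted cross-entropy plus a
Gaussian KL; high-scoring non-input pairs are predicted links.

## Worked example

```python
import numpy as np
from scdiffvae import celltype, diffvae, preprocess, synthetic

# 1. simulate a dataset: 4 cell types, 10 planted marker genes each
spec = synthetic.SyntheticSpec(n_cells=500, n_genes=200, n_clusters=4,
                               markers_per_cluster=10, seed=7)
data = synthetic.generate_expression(spec)
expr = preprocess.minmax_scale(data.expression)

# 2. train DiffVAE and extract the latent representation
config = diffvae.DiffVAEConfig(m=20, epochs=40, seed=7)
model, history = diffvae.train_diffvae(expr, config)
latent = diffvae.get_latent(model, expr)
print(f"loss: {history[0]:.2f} -> {history[-1]:.2f}")

# 3. cluster the t-SNE embedding of the latent space
embedding = celltype.tsne_embed(latent, seed=7)
clusters = celltype.cluster(embedding, "kmeans", {"n_clusters": 4, "seed": 7}, "tsne")
ari = celltype.adjusted_rand_index(data.labels, clusters.labels)
print(f"ARI vs true labels: {ari:.3f}")

# 4. marker genes from the decoder weights
relevance = celltype.dimension_relevance(latent, clusters, top_n=5)
omega = celltype.gene_weights(model, gene_names=expr.gene_names)
for c in sorted(relevance.top_dims):
    top = celltype.cluster_marker_genes(omega, relevance.top_dims[c], top_g=5)
    print(f"cluster {c}: {' '.join(top)}")
```

Output:

```
loss: 137.87 -> 127.18
ARI vs true labels: 1.000
cluster 0: g0001 g0002 g0007 g0003 g0005
cluster 1: g0033 g0032 g0034 g0031 g0037
cluster 2: g0025 g0020 g0021 g0027 g0028
cluster 3: g0018 g0016 g0015 g0011 g0010
```

The clustering recovers the four planted populations exactly (ARI 1.0), and
every reported marker is one of that cluster's planted markers (the generator
plants genes `g0000–g0009` in population 0, `g0010–g0019` in population 1,
and so on; k-means labels are arbitrary permutations of the true ones).

The same workflows are available from the shell:

```bash
scdiffvae simulate --preset small --seed 1 --out data/
scdiffvae train --input data/expression.csv --model diffvae --m 20 --epochs 40 --out run/
scdiffvae cluster --latent run/latent.csv --method kmeans --k 3 --out run/
scdiffvae markers --model run/model.h5 --latent run/latent.csv \
    --clusters run/clusters.csv --out run/
scdiffvae graph --input data/expression.csv --out run/
```

Every command writes a `manifest.json` (parameters, seed, library versions,
input checksums) next to its outputs.

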