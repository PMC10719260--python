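# gntd

Graph-guided neural tensor decomposition for imputing whole spatial
transcriptomes from sparse in-situ-capturing data.

## The problem

In-situ-capturing platforms (10x Visium and relatives) measure a gene × spot
UMI count matrix on a hexagonal array of barcoded capture spots. Low RNA
capture efficiency and section-preparation artifacts leave the measured
expression highly sparse: most gene/spot entries are zero, mixing true
biological zeros with technical dropouts. Downstream analyses — tissue
segmentation by spot clustering, spatially variable gene detection,
co-expression modules — all improve when the missing expression is imputed
first. This package is for computational biologists who want a tested,
reproducible implementation of that imputation step, together with the
simulator and evaluation protocols needed to validate it.

## The model

The observed expression is arranged as a nonnegative three-way tensor
**𝒯** ∈ ℝ₊^(n_g × n_y × n_x) over genes and the two array axes, with a
binary mask **ℳ** marking the observed (non-zero) entries. Imputation is a
neural, hierarchical form of canonical polyadic (CP) decomposition with
three layers per mode m ∈ {g, y, x}:

1. **Embedding**: linear factors A_m = E_m W_m^(emb), with E_m the identity
   one-hot embedding of the mode's index vector.
2. **Nonlinear mapping**: Ã_m = PReLU(A_m W_m^(nlin); a_m), where the
   learnable slope a_m ∈ [0, 1] interpolates between ReLU and identity.
3. **Aggregation**: a weighted CP sum with an output ReLU,
   𝒯̂ = max(Σ_i w_i Ã_g[:,i] ∘ Ã_y[:,i] ∘ Ã_x[:,i], 0).

Training minimizes

    L = ½‖ℳ ⊛ (𝒯 − 𝒯̂)‖_F² + (λ/2)·vec(𝒯̃)ᵀ (L_xy ⊕ L_g) vec(𝒯̃)

where 𝒯̃ is the pre-activation CP form, L_xy is the Laplacian of the spot
graph (each in-tissue spot joined to its 6 hexagonal neighbours and,
optionally, its 10 most expression-similar spots in the top-15 PCs), L_g is
the Laplacian of the gene graph built from protein–protein interaction
edges, and ⊕ is the Kronecker sum — the Laplacian of the Cartesian product
graph, which encourages co-expression of entries adjacent in space or in
gene function. The quadratic form factorizes over the CP factors
(Gram/Laplacian products Hadamard-weighted by wwᵀ), so the product graph is
never materialized. Optimization is full-batch Adam with analytic
gradients, a 90/10 train/validation split of the observed entries, and
validation-based early stopping.

## Worked example

Simulate a cortical-section-like dataset (7 layered regions on a 78 × 64
hexagonal grid, 50 spatially variable + 50 ubiquitous genes, 80% of tensor
entries dropped), impute it, and score the recovery:

```python
import numpy as np
from gntd import (GNTD, ProductGraph, SimulationSpec, adjusted_rand_index,
                  build_spatial_graph, cluster_spots, diagonal_gene_graph,
                  preprocess, simulate_dataset, spatial_pattern_auc, tensorize)

bundle = simulate_dataset(SimulationSpec(seed=1))
norm, grid = preprocess(bundle.to_raw_counts(), bundle.layout.grid)
tensor = tensorize(norm, grid)
graphs = ProductGraph(build_spatial_graph(grid, None),
                      diagonal_gene_graph(tensor.n_genes))
res = GNTD(tensor, graphs, rank=32, lam=0.1, seed=1).fit()
print(res.summary())
```

```
GNTD Results
==============================================
tensor shape         100 genes x 78 x 64
observed entries     61739 (12.4% of grid)
rank / nonlin. rank  32 / 32
lambda               0.1
epochs run           2000
best epoch           1990
best validation MSE  0.318527
final train loss     9105.8137
runtime              53.7 s
```

The density after dropout (12.4% of the full grid) matches the sparsity of
real Visium sections. Scoring each spatially variable gene by the
Mann–Whitney AUC of its planted high-expression spots over the rest, and
clustering spots on the imputed tensor (Gaussian mixture on 15 PCs):

```
SV-gene pattern AUC: min 0.995, mean 0.999
spot-clustering ARI vs planted regions: 0.945
```

Every planted spatial pattern is recovered almost perfectly from data in
which 80% of entries were erased, and the seven tissue regions are
recovered with ARI 0.94 (clustering the raw sparse data gives ARI ≈ 0).
`res.impute(indices)` queries individual (gene, y, x) triples;
`res.imputed_tensor()` wraps the full imputed tensor for the clustering and
evaluation helpers.

The same pipeline is scriptable from the shell:

```bash
gntd simulate --out sim/ --seed 1
gntd impute --indir sim/ --out imp/ --rank 32 --lam 0.1 --seed 1
gntd evaluate --indir sim/ --imputed imp/imputed_tensor.npy --out eval/
gntd cv --indir sim/ --out cv/ --mode spot_wise --k 10
```

Real Visium data loads through `load_counts` (Matrix Market + feature /
barcode TSVs + tissue-positions CSV) or `load_h5ad`, with a BioGRID-style
two-column TSV of gene symbols supplying the PPI gene graph.

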