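# Methods

## Data model

Spot-level expression from in-situ-capturing arrays is represented as a
nonnegative three-way tensor 𝒯 (genes × y × x) on a dense grid. Visium
array coordinates alternate column parity by row, so `(array_row,
array_col)` is compressed to `(y, x) = (array_row, array_col // 2)`; a full
Visium slide becomes a 78 × 64 grid. Out-of-tissue grid positions are kept
in the tensor as zeros with mask 0 (density statistics are quoted over the
full grid), since the tensor formulation — and the simulator calibration —
assume the complete rectangular index set. Counts are preprocessed by
counts-per-million normalization and log1p (value = log(1 + 10⁶·c/s));
spots with zero total count are dropped and genes expressed in fewer than
10 spots are removed. The observation mask follows the "observed =
non-zero" convention by default because zeros in capture-based data conflate
biological absence with dropout; `loss_on="all"` switches the
reconstruction loss to every tensor entry.

## Mode graphs and the product-graph regularizer

The spot graph joins each in-tissue spot to (i) its 6 nearest in-tissue
spots in physical hexagonal geometry and (ii) its 10 most similar spots by
Euclidean distance in the top-15 principal components of the spot × gene
matrix; the directed kNN edges are united and symmetrized, and all edges
are binary. For the spatial kNN, array coordinates are mapped to
`(array_col, array_row·√3)` first: in that metric an interior spot's six
hexagonal neighbours are exactly its nearest neighbours, whereas in raw
array units the 6-NN set is ambiguous ((r, c±2) and (r±2, c) tie). PCA is
mean-centered, unscaled, with a deterministic sign convention
(largest-magnitude loading positive). kNN ties are broken by smaller node
index. The gene graph is the binary PPI adjacency over the dataset's gene
symbols (case-insensitive matching; unmatched genes stay isolated); the
"no PPI" variant is the edgeless graph, which is identical in every model
quantity to a diagonal adjacency (W = I ⇒ L = D − W = 0).

The regularizer is the Laplacian quadratic form of the Cartesian product of
the two graphs, whose Laplacian is the Kronecker sum L_xy ⊕ L_g. On a
weighted CP tensor ⟦w; Ã_g, Ã_y, Ã_x⟧ it factorizes into exactly two
terms — a spatial term coupling (Ã_x ⊙ Ã_y)ᵀ L_xy (Ã_x ⊙ Ã_y) with the
Gram matrix of Ã_g, and a gene term coupling Ã_gᵀ L_g Ã_g with the Grams of
Ã_x and Ã_y, both Hadamard-weighted by wwᵀ. The implementation follows
this two-term identity, verified against the materialized Kronecker sum on
random small instances to 1e-8 relative error; the vectorization contract
is gene-fastest (vec = (wᵀ ⊙ Ã_x ⊙ Ã_y ⊙ Ã_g)·1), and the spatial node
ordering (node = x·n_y + y) is chosen to match it. The regularizer is
evaluated on the pre-activation CP form 𝒯̃, not on the post-ReLU output.

## Model and training

Per mode, the model is: linear embedding factors A_m = W_m^(emb) (identity
one-hot embedding), nonlinear factors Ã_m = PReLU(A_m W_m^(nlin); a_m) with
a_m ∈ [0, 1], and a weighted CP aggregation with output ReLU. The
hierarchy is fixed at two layers; the nonlinear rank ñ_r defaults to the CP
rank n_r (rank grid {8, 16, 32, 64, 128}, default 64; λ default 0.1).

Training is full-batch Adam (β = 0.9/0.999, ε = 1e-8) on analytic
gradients; full-batch because the factorized regularizer is a whole-factor
quantity. The observed entries are split 90/10 into train/validation by
the run seed (inside cross-validation the split is drawn from the training
mask only, after test entries are hidden). Validation MSE is monitored;
after a 1000-epoch warm-up, training stops after 50 epochs without
improvement and the best-validation snapshot is returned. The PReLU slopes
are constrained to [0, 1] by clamping after each step.

Two optimization choices required care, both settled by experiments on the
default simulation:

- **Initialization.** Weights start uniform in [−1/√n_r, 1/√n_r] (the
  standard fan-in range), slopes at 0.25, w at 1. An all-positive start is
  unstable here: initial predictions sit far below the data magnitude
  (log-CPM values ≈ 10), the first adaptive full-batch steps overshoot, the
  pre-ReLU tensor swings negative on every observed entry, and the output
  ReLU then blocks all reconstruction gradient — the loss freezes at
  ½Σℳ𝒯². The mixed-sign start trains robustly across seeds and λ.
- **Learning rate.** The initial rate is 0.05, halved whenever the
  validation MSE stalls for 25 epochs (floor 1e-3). Without the
  decay-on-plateau schedule, large-λ or unregularized fits at realistic
  scale can oscillate indefinitely or collapse through the ReLU dead zone.

Non-finite losses abort with diagnostics rather than silently diverging.

## Simulator

The generator emulates a cortical section: an elliptical tissue footprint
on a parity-aware hexagonal grid (default 78 × 64, coverage 0.73 — the
in-tissue set is exactly the target number of grid positions closest to the
center in the elliptical metric, ≈ 3,640 spots) banded into 7 contiguous
layer-like regions of equal size. Each spatially variable gene draws
r ~ U{10..100}, picks 1–3 high regions uniformly, and samples counts from
NB(r, p = 0.85) in high regions and NB(r/2, p = 0.95) elsewhere; ubiquitous
genes sample NB(r ~ U{5..50}, p = 0.85) everywhere in tissue. The NB is
parameterized as failures before r successes with success probability p
(mean r(1−p)/p) — the numpy/scipy convention, and the reading under which
the low-region distribution is in fact lower than the high-region one.
Dropout is mimicked by forcing exactly ⌊ρN⌋ of all N tensor entries
(already-zero and out-of-tissue included) to zero uniformly at random. At
ρ = 0.8 this yields a full-grid density of ≈ 12–13%, matching sparse
Visium sections; the generator's defaults are the study conditions and are
not tuned per run.

What the simulator does not model: spot-specific library size or capture
efficiency, spatially correlated dropout, irregular region shapes, or gene–
gene correlation beyond the shared region structure. Passing tests on this
synthetic family therefore demonstrate pattern recovery under uniform
dropout with layered regions, not performance on arbitrary real tissue.

### Evaluation protocol on simulated data

For simulated data the spot graph uses only the 6-NN hexagonal edges and
the gene graph is edgeless. At 80% inflation with 100 genes the spot
principal components are essentially noise (the top PC explains ≈ 1.5% of
variance), so expression-similarity edges connect spots at chance level
with respect to region identity (≈ 15% within-region); including them
injects cross-region smoothing that blurs the planted patterns and inverts
the expected benefit of regularization. The positional-only graph is the
protocol consistent with the simulation's purpose (and with its simplified,
edgeless gene graph); the full 6-NN + 10-NN construction remains the
default for real data, where the co-expression neighbourhood carries
signal.

## Evaluation

Cross-validation covers only observed entries. Spot-wise: spots are
randomly split into k = 10 folds and every observed entry inherits its
spot's fold. Gene-wise: each gene's observed entries are dealt across
folds so per-fold counts differ by at most one (genes with fewer than k
entries span fewer folds, logged). Fold predictions are combined before
metric computation; RMSE/MAE/MAPE/R² are computed per spot (or per gene)
and averaged, units without test entries excluded. MAPE is defined only
over non-zero truth, which the CV design guarantees. R² may be negative
and is NaN for constant truth vectors.

Spot clustering is a Gaussian mixture on the top 15 PCs (full covariance,
k-means initialization, 10 restarts, best likelihood kept, seeded —
choices standing in for mclust's internal model selection); optional
restriction to the top 2,000 genes by dispersion. Gene clustering is
k-means (k = 100) on the top 50 PCs of the gene × spot matrix. Partition
agreement is the adjusted Rand index (contingency form; two single-cluster
partitions score 1). Pattern recovery per gene is the Mann–Whitney AUC of
high-region spots over the rest under the imputed expression, with average
ranks for ties.

## Numerical notes and limitations

- The quadratic form is clipped to 0 only when roundoff produces a value in
  (−1e-8, 0); a genuinely negative value would indicate a bug and is
  returned unclipped.
- Degenerate configuration a_m = 1, W^(nlin) = I, w = 1 reduces the forward
  model to plain CP reconstruction exactly (up to float reassociation);
  this anchors the model against a brute-force CP oracle in the tests.
- Problem sizes in the test suite: the full simulation study runs at its
  native scale (100 × 78 × 64, rank 32); the cross-validated λ comparison
  uses 2 folds, and oracle checks use tensors with ≤ 5 nodes per mode.
- Full determinism given (config, seed) holds for training, simulation,
  folds and clustering; imputed tensors are reproducible bit-for-bit on a
  fixed platform, though BLAS reassociation may introduce ~1e-15 relative
  differences across platforms.
- The model is defined on 2-D grids; probe-based platforms needing cell
  segmentation, 3-D stacks, and histology integration are out of scope.
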