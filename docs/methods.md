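# Methods

## Overview

`cellforge` generates labelled single-cell RNA-seq count matrices with a
latent denoising diffusion probabilistic model (DDPM).  The pipeline has
three learned parts and one fixed transform:

1. **Normalization.**  Raw counts X are library-size normalized per cell,
   v_ij = ln(10⁴ · x_ij / Σ_j x_ij + 1): each cell's total is scaled to
   10 000, offset by 1 and log-transformed.  This stabilizes variance and
   puts the data on a scale the Gaussian diffusion process can work with.
   Cells with zero total counts map to all-zero rows (with a warning)
   rather than NaNs.
2. **Autoencoder.**  A 2-layer MLP encoder maps normalized expression to a
   low-dimensional latent embedding (default 128, desk-scale preset 32); a
   3-layer MLP decoder maps back.  ReLU hidden activations, linear heads
   (the latent and the output must cover the real line / the log-expression
   range without clipping).  Trained with Adam on the squared Frobenius
   reconstruction error.  The layer counts are part of the architecture
   contract; the widths are free parameters.
3. **Conditional diffusion in latent space.**  A DDPM with T discrete steps
   (default 1000; desk-scale 200) and a linear β schedule from 1e-4 to 0.02
   learns to predict the corruption noise ε from (x_t, t, y).  Labels enter
   by classifier-free guidance: during training each label is replaced by a
   reserved null index with probability 0.1, so one network learns both the
   conditional and the unconditional score.  At sampling time the two
   predictions are combined as ε̂ = ε_u + w (ε_c − ε_u).
4. **Count reconstruction.**  Generated latents are decoded and inverted
   through the normalization: decoded values become per-gene shares
   (exp(v) − 1), renormalized per cell, scaled by a library size resampled
   from the real cells of the same class, and stochastically rounded
   (floor + Bernoulli on the fractional part) to integer counts.  Stochastic
   rounding keeps per-gene expected counts unbiased; renormalization makes
   the inversion robust to scale drift in the decoder output while being a
   no-op on exactly-normalized input.

### Latent standardization

Diffusion operates on per-dimension standardized latents ((z − μ)/σ over
the training embedding).  The forward process mixes signal with
unit-variance noise; on the encoder's arbitrary output scale the noise
would be essentially unrecoverable at most steps and training would stall
at the trivial (zero-prediction) optimum.  μ and σ are stored with the
model and inverted before decoding.

## Backbone

The noise predictor is a symmetric stack of MLP "chunks" in a U-Net-like
arrangement, all fully connected — expression vectors have weak
neighbour-order structure, so convolutions offer nothing over dense layers.
For depth d (default 2) the conditioned chunks are D₁…D_d, mid, U₁…U_d
(an odd count 2d+1), followed by a two-layer fully-connected head
FC₁, FC₂.  Each chunk applies

    x ← x ⊙ proj_y(E[y]) + proj_t(temb(t))

— an elementwise product with a chunk-projected learned label embedding
plus a chunk-projected sinusoidal time embedding — and then a 2-layer MLP.
The label projection's bias initializes at 1 so the product starts
near-identity and early gradients are not multiplicatively destroyed.
Down-chunk outputs are pushed on a stack; each up-chunk adds the popped
top to its output, so U_i receives the skip of D_{d+1−i} (LIFO).  The head
sits outside the skip symmetry.

### Cached inference

Deep features change slowly between adjacent reverse steps, so the deep
half of the backbone can be skipped most of the time.  A cache schedule ξ
(fixed interval c, default 5, or a cycled interval list) marks the steps at
which the full backbone runs and the input to up-chunk U_b (the post-skip
output of the stage before it) is saved.  All other steps run the truncated
pass: only the shallow down chunks needed for the remaining skips
(D₁…D_{d+1−b}), then U_b…U_d applied to the saved feature with
conditioning at the *current* step, then the head.  For d = b = 2 the
cached pass touches exactly {D₁, U₂, FC₁, FC₂}.  The first reverse step
T−1 is always in ξ, and each guidance branch (conditional/unconditional)
keeps its own cached feature.  With c = 1 the cache is refreshed before
every use, so the sampler output is bit-identical to uncached sampling —
the mechanism is purely a compute-reduction, not an approximation knob, at
that setting.  Compute is reported as full/cached pass counters rather
than wall time, which makes the saving hardware-independent and testable.

### Sampling conventions

Steps are indexed t ∈ {0, …, T−1}.  The sampler starts from x ~ N(0, I)
and visits every index once (T backbone evaluations per branch).  Reverse
updates use the posterior mean with fixed variance β_t I; the updates at
t = 1 and the final refinement at t = 0 add no noise.  The guidance
hyperparameter k maps to the interpolation weight via `weight_form`:
`"k"` (default, w = k, so k = 1 is the pure conditional model) or
`"1+k"` (w = 1 + k, the expansion ε_c − k(ε_u − ε_c)).  Both are exposed
because the two published forms of the combination rule disagree; the
useful range of k is 1–2 either way.

## Synthetic data generator

The generator emulates the statistical structure the pipeline is meant to
handle, with no download:

- **Counts** are negative binomial — the standard over-dispersed model for
  UMI data.  The generative model under test makes no distributional
  assumption, so the fixture only needs realistic structure.
- **Groups**: one per combination of attribute levels (1 or 2 attributes;
  paired attributes give the full factorial, e.g. organ × cell type).
  Each group elevates a random `marker_fraction` of genes to means drawn
  from `nb_mean_range`.
- **Baseline heterogeneity**: non-marker means are drawn once per gene,
  log-uniform over [baseline_mean/5, baseline_mean·5], shared across
  groups.  Real genes span orders of magnitude in background expression; a
  flat baseline would also make per-gene mean *ranks* pure sampling noise
  and rank-based quality metrics uninformative (two independent draws of a
  flat-baseline process correlate at only ρ ≈ 0.6; with heterogeneous
  baselines the independent-draw ceiling is ≈ 0.99).
- **Defaults** (the study conditions used throughout the tests): 200
  genes, 300 cells per group, 3 cell types, baseline_mean 0.1, dispersion
  0.3, marker_fraction 0.1, markers in [2, 8].  Empirical zero fraction
  ≈ 0.84–0.87, inside the 83–97% band of real droplet/InDrop/10X
  datasets.
- **Trajectories**: group means interpolate linearly between two profiles
  across `n_timepoints`, labelled by time index — a discrete stand-in for
  pseudo-time series.
- **Dropout injection** zeroes exactly round(rate · n_genes) entries per
  cell, uniformly without replacement, so tests can assert exact counts.

What the generator does **not** emulate: gene–gene correlation beyond the
group structure, batch effects, ambient RNA, doublets, UMI saturation.
Passing tests therefore show that the method recovers group-conditional
count distributions under realistic sparsity and dispersion — not that it
handles every artefact of real data.

## Evaluation suite

All metrics compare a (real, generated) pair on matched genes, in
normalized space unless noted.

- **SCC / PCC**: Spearman and Pearson correlation of the per-gene mean
  expression vectors (means over cells, per gene).  Ties in SCC get
  average ranks, which coincides with the classical 1 − 6Σd²/(n(n²−1))
  formula when there are no ties.
- **MMD**: Gaussian-kernel maximum mean discrepancy on a PCA fitted to the
  concatenated samples (default 50 components), unbiased U-statistic,
  bandwidth from the median heuristic on pooled pairwise distances.  A
  permutation test (kernel computed once, labels reshuffled) provides a
  calibrated null.
- **Wasserstein**: mean of 1-D Wasserstein-1 distances over the leading
  joint PCs.  The PC-wise form is this package's convention (cheap and
  deterministic); other conventions (per-gene, sliced-random) exist.
- **ILISI**: cells pooled with a real/generated batch label, joint PCA,
  inverse Simpson index 1/Σ_b p_b² over the batch proportions among each
  cell's k = 30 nearest neighbours, min-max normalized to [0, 1] with
  B = 2 and averaged.  Implemented from the definition (self-contained).
  Note the finite-k ceiling: even perfectly interleaved equal batches give
  a mean around 0.85–0.9, not 1, because neighbourhood proportions
  fluctuate binomially around ½.
- **RF / KNN discriminability**: label real vs generated, stratified
  5-fold random forest (100 trees) and a 70/30 k-nearest-neighbour split
  (k = 5); accuracy near 0.5 means indistinguishable.  AUC is reported
  alongside.
- **ARI / NMI**: agreement between a clustering of the generated cells and
  their own requested labels.  External partitions (e.g. Leiden) can be
  supplied; the built-in hook is k-means on leading PCs with one cluster
  per label level.  Clustering internals are out of scope.
- **QQ quantiles**: paired quantile tables of z-scored columns (z-scoring
  over the whole matrix), for plotting against y = x.

## Numerical choices and degenerate inputs

- All network code is float64 numpy with manual backprop and Adam
  (lr 1e-3, β = (0.9, 0.999)); single-threaded runs are bit-reproducible
  for a fixed seed.
- All-zero cells normalize to all-zero rows; constant vectors make
  correlation metrics raise rather than return NaN.
- Counts are stored sparse (CSR) when density < 50% and densified only
  inside training batches.
- The desk-scale study size (200 genes, 900 cells, latent 32, T = 200,
  16 000 diffusion steps, AE 800 epochs at width 256) is the package's
  default experiment: large enough that the quality gates are meaningful,
  small enough to train on one CPU in a few minutes.

## Known limitations

- The decoder smooths per-cell sampling noise, so generated cells have a
  slightly higher zero fraction and slightly tighter per-gene marginals
  than real cells; neighbourhood-mixing scores saturate around 0.65–0.70
  on the desk-scale study rather than the finite-k ceiling.
- The label vocabulary is closed at training time; generating an unseen
  attribute combination requires retraining.
- Dynamic cache schedules are exposed but the defaults use a fixed
  interval; no error-adaptive refresh policy is implemented.
- Checkpoints store raw weight arrays with a versioned JSON header; they
  are not portable across incompatible architecture configs.
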