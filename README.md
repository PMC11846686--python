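# cellforge

Conditional generation of single-cell RNA-seq count data with a latent
diffusion model, classifier-free guidance, and cached-feature fast
sampling — plus the synthetic benchmark generator and evaluation suite
needed to test every stage end to end on one CPU.

## Who this is for

Downstream scRNA-seq analyses (cell-type annotation, differential
expression, trajectory inference) suffer when some cell populations are
rare or hard to sequence.  Generative augmentation addresses this by
learning the distribution of real cells and sampling new ones of a
requested type.  `cellforge` is for computational biologists who want a
conditional generator that (a) makes no parametric assumption about the
count distribution, (b) conditions on one or two categorical attributes
(cell type, organ, time point) with a single network and no auxiliary
classifiers, and (c) samples fast enough to be practical.

## The model

Counts X are normalized per cell, v = ln(10⁴ · x / Σx + 1), and embedded
by a 2-layer MLP encoder into a low-dimensional latent x₀; a 3-layer MLP
decoder maps back.  A denoising diffusion probabilistic model (DDPM) is
trained on the standardized latents: the forward process corrupts by

    x_t = √ᾱ_t x₀ + √(1 − ᾱ_t) ε,   ε ~ N(0, I),  ᾱ_t = Π_{i≤t}(1 − β_i)

and a conditioned MLP U-Net ε_θ(x_t, t, y) is trained to predict ε by mean
squared error.  Labels enter by **classifier-free guidance**: during
training, y is replaced by a null token with probability 0.1; at sampling
the conditional and unconditional predictions combine as

    ε̂ = ε_u + w (ε_c − ε_u)

so one network serves every condition, including paired attributes
(e.g. organ × cell type) through a joint label vocabulary.

Reverse-process inference is accelerated by **high-level feature
caching**: at scheduled steps ξ = {T−1, T−1−c, …} (skip interval c,
default 5) the full backbone runs and the input to a deep up-chunk is
saved; in between, only the shallow chunks and the head are evaluated on
the cached feature.  At c = 1 the output is bit-identical to uncached
sampling; at c = 5 each guidance branch takes 200 full and 800 cached
passes instead of 1000 full ones (T = 1000).  Generated latents are
decoded and inverted to integer counts with library sizes resampled from
the real cells of the requested class.

See `docs/methods.md` for the full methods note.

## Worked example

Train on a seeded synthetic dataset (3 negative-binomial cell types,
200 genes, 300 cells per type, ~86% zeros), generate a matched dataset at
cache interval 5, and score it:

```python
import json, cellforge as cf

real   = cf.make_dataset(cf.SyntheticConfig(seed=0))
model  = cf.fit(real, seed=0)                       # AE + guided diffusion, ~2.5 min CPU
gen    = cf.generate_matched(model, cache_interval=5, seed=0)
report = cf.evaluate(cf.normalize(real), cf.normalize(gen), seed=0)
d = report.to_dict(); d.pop("settings")
print(json.dumps({k: round(v, 4) for k, v in d.items()}, indent=2))
```

prints

```json
{
  "scc": 0.9861,
  "pcc": 0.9821,
  "mmd": 0.0246,
  "ilisi": 0.6713,
  "wasserstein": 0.3822,
  "rf_accuracy": 0.7972,
  "knn_accuracy": 0.4944,
  "auc": 0.8605,
  "ari": 0.9117,
  "nmi": 0.8644
}
```

Reading the numbers: per-gene mean expression of generated cells ranks and
correlates with the real data at ρ, r ≈ 0.98 (> 0.9 is the usual quality
bar); a random forest told real from generated only 80% of the time and a
KNN classifier not at all (0.49 ≈ chance); the neighbourhood-mixing score
ILISI 0.67 is above the 0.5 diversity threshold; and k-means clusters of
the generated cells agree with their requested type labels at ARI 0.91.

The same pipeline is scriptable from the shell:

```bash
cellforge simulate --seed 0 --out real.h5ad
cellforge train    --inp real.h5ad --seed 0 --out model.npz
cellforge generate --model model.npz --label type_1 --n 300 --skip 5 \
                   --seed 0 --out gen.h5ad
cellforge evaluate --real real.h5ad --gen gen.h5ad --out report.json
```

Matrix Market (+ barcodes/features TSVs), dense CSV, and h5ad formats are
supported throughout (`--fmt`).

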