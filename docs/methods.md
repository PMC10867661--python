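# Methods

## Model and training protocol

The denoiser is an adversarial autoencoder over preprocessed expression
profiles. Per training step on batch x_b:

1. the encoder produces the authentic latent code z_b = l_e(x_b) and the
   decoder the reconstruction x′_b = l_d(z_b); both are updated on the
   binary-cross-entropy reconstruction loss L_rec;
2. the generator path re-encodes the **previous** batch's reconstruction,
   n_r = l_e(x′_prior), scores it with the discriminator, and updates the
   encoder on L_gen; on the very first step, where no prior reconstruction
   exists, the current batch's own reconstruction (computed without
   gradients) stands in;
3. the discriminator is updated on L_disc over D(z_b) (authentic) versus
   D(n_r) (simulated). When the prior batch is shorter than the current one
   (the kept, incomplete last batch of an epoch), both sides are truncated to
   the common length, preserving the equal-length form of the loss.

Each of the three updates has its own RMSprop accumulator (ρ = 0.9,
ε = 1e-8); the encoder receives updates from both the reconstruction and the
generator path. All probabilities are clipped to [1e-7, 1 − 1e-7] before any
logarithm, and the clip zeroes the corresponding gradient.

Two generator-loss modes are provided. The default `paper` mode is
L_gen = −mean log(1 − D(fake)) exactly as the architecture defines it; note
that minimizing this form rewards the encoder for making simulated latents
*easy* to detect — the reverse of the conventional non-saturating GAN
objective, which is available as mode `nonsaturating`
(−mean log D(fake)). The default is kept verbatim rather than silently
"fixed"; in the regimes tested the reconstruction loss dominates training
either way.

Activation choices: hidden layers are LeakyReLU (negative slope 0.2, a
package default — the slope is otherwise unspecified). The published
architecture puts ReLU on the final layer of encoder, decoder and
discriminator, but the generator and discriminator losses take log D and
log(1 − D) and the reconstruction loss is a cross-entropy over [0, 1]
targets, so ReLU outputs would leave them undefined or unbounded. The
decoder and discriminator therefore end in sigmoid by default
(configurable, with ReLU-plus-clipping available for the decoder); the
encoder output keeps ReLU. A consequence worth knowing: roughly half the
latent units are dead at initialization under a ReLU latent, so narrow
latent widths underperform — widths are chosen with headroom (512 in the
published configuration, 64 in the scaled preset).

Training runs whole epochs with seeded shuffling; the last incomplete batch
is kept so every cell is reconstructed. The published stopping rule
("until the discriminator can no longer differentiate") has no stated
threshold, so final training defaults to 300 epochs with early stopping on a
reconstruction-loss plateau (patience 20 epochs, tolerance 1e-5).

## Dynamic batch-size search

Candidates form the grid {start, start+step, …, end} clipped to the number
of cells (default 32..256 step 32). Each candidate trains a **fresh** model
(per-candidate seeds spawned from the search seed) for `epochs_per_cycle`
epochs; restarting fresh keeps records comparable across candidates. A cycle
records the minimum reconstruction loss over its steps and a cycle-end
"accuracy", defined here — the term is otherwise undefined — as
1 − mean absolute reconstruction error on a held-out 10% cell split, so it
is denoising-relevant and bounded in [0, 1]. Selection is lexicographic:
lowest minimum loss, ties broken by higher accuracy, then by smaller batch
size; the selector is a pure function of the record table, so a stored table
replays to the identical choice. The exhaustive sweep is the default
strategy; a successive-halving mode (`hyperband`) that prunes the weaker
half of candidates at each rung is available for larger grids.

## Preprocessing

Genes are ranked by mean-binned normalized dispersion: dispersion is
variance/mean of (by default) log1p counts, standardized within 20
equal-count mean bins; ties break deterministically by gene index and
zero-variance genes rank last. The top `n_top` genes (default
min(n_genes, 2000)) are z-scored per gene. The divisor σ_m is the plain
per-gene standard deviation (ddof = 0) by default; a `trend` mode instead
uses the expected standard deviation from a quadratic mean–variance trend
fitted on the log scale, for users who read σ_m as a fitted global quantity.
Zero-variance genes get z = 0 and are flagged. Because the reconstruction
loss is a binary cross-entropy, z-scores are then min-max mapped per gene
into [0, 1] (constant columns map to 0.5). Every step stores its inversion
parameters; the full inverse (unit interval → z-scores → log1p expression →
counts scale) recovers the input to ~1e-8 relative error. Whether any
library-size normalization precedes the z-score is left to the caller: the
log1p transform is a flag, and no depth normalization is imposed.

Denoised output is returned on the z-score scale by default (the network's
native scale after inversion of the min-max map), with an `expression`
option that continues through the stored means/sds and expm1.

## Synthetic data

The simulator emulates the gamma-Poisson hierarchy of the Splatter
generator: baseline gene means ~ Gamma(shape 0.6, rate 0.3); per-cell
library sizes ~ LogNormal(7.0, 0.2) (expected total ≈ 1,100 counts over 200
genes); with probability `de_prob` = 0.3 a gene is differentially expressed
in a group, with multiplicative factor 2^N(0, 1); group expression
proportions are renormalized so library size keeps its meaning; counts are
Poisson around libsize × proportion. Dropout zeroes entry (c, g)
independently with probability
p = 1/(1 + exp(−shape · (midpoint − ln(1 + μ_cg)))) where μ_cg is the entry's
pre-sampling expected value — the logistic-of-log-mean mechanism of the
cited simulator, applied at entry level with an explicit recorded mask.
Defaults midpoint 2.0, shape 1.5 put typical log-means just below the
midpoint and zero roughly two thirds of entries, a deliberately harsh
regime in which the raw six-group silhouette collapses to ≈ 0. All preset
values are package defaults, not published ones.

Directionality note: with this parameterization, increasing `shape` raises
the zeroing probability only for entries whose log expected value lies
*below* the midpoint; when the midpoint sits at or above the typical
log-mean the expected zero fraction is monotone non-decreasing in `shape`,
and the property test asserts exactly that regime.

What the simulator does **not** emulate: biological-coefficient-of-variation
trends, batch effects, trajectories/paths, doublets, or ambient RNA. Passing
benchmarks on these data therefore demonstrates recovery of discrete group
structure under Poisson noise and logistic dropout — not performance on the
full messiness of real tissue atlases.

## Problem sizes and the scaled preset

Unit and acceptance runs use 200 genes × 500 cells with a proportionally
shrunk network (encoder 200–128–64, latent 64, discriminator 64–32–1): the
published shape at roughly an eighth scale. At these sizes the published
learning rate of 2e-5 would need tens of thousands of optimizer steps to
leave the underfit regime, so the scaled preset raises it to 1e-3; the
published values remain the package defaults for full-size data. A useful
diagnostic pair for any run: the entropy floor of the [0,1] targets (the
BCE of a perfect reconstruction, ≈ 0.19 on the benchmark data) versus the
achieved L_rec. Training quality matters in both directions — underfit
models reproduce noise directions and can *lower* the silhouette, and very
long training eventually overfits the dropout zeros; a few hundred epochs
at the scaled sizes sits in the regime where the bottleneck has captured
the group manifold but not the noise.

## Numerical and degenerate-input conventions

- Identical config + seed ⇒ bit-identical simulated counts, training
  trajectory and denoised output (pure NumPy, single-threaded semantics).
- Silhouette: exact pairwise-distance implementation (Euclidean default);
  singleton-cluster cells get s_i = 0 and are flagged; a single cluster is an
  error. Scores are computed directly on the supplied matrix (z-scores or
  denoised values); any precomputed embedding can be passed instead.
- Pseudo-time r²: numeric stage vectors are used as-is; categorical stages
  map to 0, 1, 2, … in category/appearance order. Zero variance in either
  vector yields a flagged undefined result, not r² = 0.
- Weight initialization is seeded Glorot-uniform; biases start at zero.
- Oversized batch sizes clip to n_cells with a warning; an empty candidate
  grid, non-finite losses, or a mismatched matrix width raise immediately
  with the offending quantity named.

## Known limitations

- The `paper`-mode generator loss is kept verbatim despite its reversed
  sign convention (see above); users wanting conventional adversarial
  pressure should select `nonsaturating`.
- "Accuracy" in the search records is a package definition (held-out
  1 − MAE), not a published formula.
- The simulator's parameter presets are package defaults; quantitative bar
  heights from any particular simulated figure are not reproducible, only
  the qualitative ordering (dropout degrades clustering; denoising restores
  it; clean data is left intact).
- Training is CPU-oriented NumPy; it is deterministic and adequate for
  hundreds to a few thousands of cells, but no GPU path is provided.
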