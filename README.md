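# dbaae

Dropout denoising for single-cell RNA-seq count matrices with a
**dynamic-batching adversarial autoencoder (DB-AAE)**, plus the synthetic-data
simulator and evaluation statistics needed to exercise it end to end without
downloading any dataset.

scRNA-seq count matrices are riddled with technical zeros ("dropout"):
transcripts present in a cell but missed by capture and sequencing. These
excess zeros blur cell-type structure and derail clustering and trajectory
analysis. `dbaae` is aimed at computational biologists who want to impute
those entries before downstream analysis, and at method developers who need a
self-contained, fully seeded benchmark harness.

## The model

An adversarial autoencoder trained per mini-batch x_b of the preprocessed
expression matrix:

- **encoder** l_e (dense, input–1024–512–512, LeakyReLU) maps x_b to the
  *authentic* latent code z_b = l_e(x_b);
- **decoder** l_d mirrors the encoder and reconstructs x′_b = l_d(z_b), with a
  sigmoid output so values stay in [0, 1];
- **generator path** re-encodes the *previous* batch's reconstruction to make
  a *simulated* latent code n_r = l_e(x′_prior);
- **discriminator** D (512–256–1, sigmoid output) scores latent codes as
  authentic vs simulated.

Losses, all averaged over the batch:

```
L_rec  = −(1/N) Σ [x log x′ + (1 − x) log(1 − x′)]        (binary cross-entropy)
L_gen  = −(1/N) Σ log(1 − D(l_e(x′)))
L_disc = −(1/N) Σ [log D(l_e(x)) + log(1 − D(l_e(x′)))]
```

All three networks use RMSprop at learning rate 2e-5 (package default).
The **dynamic batching** layer sweeps candidate batch sizes over a
start/end/step grid, trains a short cycle per candidate, records each cycle's
minimum reconstruction loss and held-out accuracy, picks the winner
(lowest loss, ties to higher accuracy, then smaller batch), and runs the
final training at that size. The denoised matrix is the union of the
per-batch reconstructions, inverse-transformed back to the z-score (or
expression) scale.

The simulator draws gamma-distributed gene means, log-normal library sizes
and group-wise log-normal DE factors, Poisson counts around their product,
and — optionally — logistic-of-log-mean dropout with an explicit mask, so the
ground truth for every benchmark is known. Evaluation uses the mean
silhouette s_i = (b_i − a_i)/max(a_i, b_i) over true labels and, for
trajectories, the squared Pearson correlation r² between a supplied
pseudo-time vector and annotated stages.

## Worked example

Simulate a six-group, 200-gene × 500-cell matrix with dropout, denoise it
with the scaled network preset, and compare clustering quality:

```python
from dbaae import fig2_preset, simulate_counts, normalize, silhouette
from dbaae.presets import scaled_model
from dbaae.aae import AAEModel, train
from dbaae.preprocess import inverse_rescale

data = simulate_counts(fig2_preset(6, n_cells=500, dropout=True, seed=1))
norm = normalize(data, n_top=200)
raw = silhouette(norm.z_scores, data.cell_labels).mean_silhouette

model = AAEModel(scaled_model(input_dim=200, seed=1))
train(model, norm.values, batch_size=64, epochs=300, seed=1)
denoised_z = inverse_rescale(norm, model.reconstruct_full(norm.values, 64))
den = silhouette(denoised_z, data.cell_labels).mean_silhouette

print(f"mean silhouette, raw dropout matrix: {raw:.3f}")
print(f"mean silhouette, denoised matrix:    {den:.3f}")
```

Output:

```
mean silhouette, raw dropout matrix: 0.012
mean silhouette, denoised matrix:    0.116
```

Dropout has almost erased the six-group structure in the raw z-scores
(silhouette ≈ 0); after denoising, cells of the same simulated type are
markedly closer to each other than to other types. The same chain is
available from the shell:

```bash
dbaae simulate --genes 200 --cells 2000 --groups 6 --dropout --seed 1 --out sim.h5ad
dbaae denoise  --input sim.h5ad --out denoised.h5ad --seed 1
dbaae evaluate --input denoised.h5ad --labels cell_type --layer dbaae_denoised
```

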