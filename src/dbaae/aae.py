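"""Adversarial autoencoder core: networks, losses, and the training step.

Three dense networks — encoder, decoder (mirror of the encoder) and
discriminator — are trained jointly.  The encoder maps a batch of [0,1]-scaled
expression profiles to its "authentic" latent code z_b; the generator path
re-encodes the *previous* batch's reconstruction to produce a "simulated"
latent code n_r; the discriminator is trained to tell the two apart while the
encoder (through the generator loss) and the autoencoder (through a binary
cross-entropy reconstruction loss) are updated against it.

Everything is plain NumPy with explicit backpropagation and per-network
RMSprop states, which makes runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EPS = 1e-7  # probability clipping before any log


# ---------------------------------------------------------------------------
# activations

def _act(name: str, x: np.ndarray, slope: float) -> np.ndarray:
    if name == "leaky_relu":
        return np.where(x > 0, x, slope * x)
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, x: np.ndarray, out: np.ndarray, slope: float) -> np.ndarray:
    if name == "leaky_relu":
        return np.where(x > 0, 1.0, slope)
    if name == "relu":
        return (x > 0).astype(float)
    if name == "sigmoid":
        return out * (1.0 - out)
    if name == "linear":
        return np.ones_like(x)
    raise ValueError(f"unknown activation {name!r}")


class MLP:
    """Dense stack with per-layer activations and manual backprop."""

    def __init__(
        self,
        dims: list[int],
        hidden_activation: str,
        final_activation: str,
        leaky_slope: float,
        rng: np.random.Generator,
    ):
        self.dims = list(dims)
        self.leaky_slope = leaky_slope
        self.activations = [hidden_activation] * (len(dims) - 2) + [final_activation]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def in_dim(self) -> int:
        return self.dims[0]

    @property
    def out_dim(self) -> int:
        return self.dims[-1]

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray):
        """Return (output, cache) where cache holds pre/post-activation values."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.in_dim:
            raise ValueError(
                f"input width {x.shape[-1] if x.ndim == 2 else x.shape} does not "
                f"match network input width {self.in_dim}"
            )
        hs, pre, h = [x], [], x
        for W, b, act in zip(self.W, self.b, self.activations):
            a = h @ W + b
            h = _act(act, a, self.leaky_slope)
            pre.append(a)
            hs.append(h)
        return h, (hs, pre)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, grad_out: np.ndarray, cache):
        """Backpropagate dLoss/d(output); return (param_grads, grad_input)."""
        hs, pre = cache
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        delta = grad_out
        for i in range(len(self.W) - 1, -1, -1):
            delta = delta * _act_grad(self.activations[i], pre[i], hs[i + 1], self.leaky_slope)
            gW[i] = hs[i].T @ delta
            gb[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
        return gW + gb, delta


class RMSprop:
    """Root-mean-square propagation with one accumulator per parameter."""

    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v: list[np.ndarray] | None = None

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.v):
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# losses (pure functions, each mirrored by a scalar-loop oracle in the tests)

def reconstruction_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean element-wise binary cross-entropy between input and reconstruction."""
    x = np.asarray(x, dtype=float)
    xp = np.asarray(x_prime, dtype=float)
    if x.shape != xp.shape:
        raise ValueError("input and reconstruction shapes differ")
    xp = np.clip(xp, EPS, 1.0 - EPS)
    return float(-np.mean(x * np.log(xp) + (1.0 - x) * np.log(1.0 - xp)))


def generator_loss(d_fake: np.ndarray, mode: str = "paper") -> float:
    """Generator loss over discriminator outputs on simulated latents.

    ``paper`` mode is the printed form -mean log(1 - D(fake)); the
    ``nonsaturating`` alternative is the conventional -mean log D(fake).
    """
    d = np.asarray(d_fake, dtype=float)
    if ((d < 0) | (d > 1)).any():
        raise ValueError("discriminator outputs must lie in [0, 1]")
    d = np.clip(d, EPS, 1.0 - EPS)
    if mode == "paper":
        return float(-np.mean(np.log(1.0 - d)))
    if mode == "nonsaturating":
        return float(-np.mean(np.log(d)))
    raise ValueError(f"unknown generator loss mode {mode!r}")


def discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """-mean[log D(real) + log(1 - D(fake))]."""
    dr = np.asarray(d_real, dtype=float)
    df = np.asarray(d_fake, dtype=float)
    if dr.shape != df.shape:
        raise ValueError("d_real and d_fake lengths differ")
    if ((dr < 0) | (dr > 1)).any() or ((df < 0) | (df > 1)).any():
        raise ValueError("discriminator outputs must lie in [0, 1]")
    dr = np.clip(dr, EPS, 1.0 - EPS)
    df = np.clip(df, EPS, 1.0 - EPS)
    return float(-np.mean(np.log(dr) + np.log(1.0 - df)))


@dataclass
class StepLosses:
    L_rec: float
    L_gen: float
    L_disc: float

    @property
    def a_loss(self) -> float:
        """Combined adversarial loss of the step."""
        return self.L_gen + self.L_disc

    def check_finite(self) -> None:
        for name in ("L_rec", "L_gen", "L_disc"):
            if not np.isfinite(getattr(self, name)):
                raise FloatingPointError(f"non-finite loss term {name}")


# ---------------------------------------------------------------------------
# the model

@dataclass
class AAEConfig:
    """Architecture and optimization hyperparameters.

    Defaults are the published ones: encoder input-1024-512-512 (latent width
    512), discriminator 512-256-1, LeakyReLU hidden activations, RMSprop at
    learning rate 2e-5 for all three networks.  The decoder mirrors the
    encoder.  Decoder and discriminator outputs default to sigmoid so the
    cross-entropy losses stay defined.
    """

    input_dim: int = 0
    encoder_hidden: tuple[int, ...] = (1024, 512)
    latent_dim: int = 512
    disc_hidden: tuple[int, ...] = (256,)
    learning_rate: float = 2e-5
    leaky_slope: float = 0.2
    encoder_final: str = "relu"
    decoder_final: str = "sigmoid"
    disc_final: str = "sigmoid"
    gen_loss_mode: str = "paper"
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["encoder_hidden"] = list(self.encoder_hidden)
        d["disc_hidden"] = list(self.disc_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AAEConfig":
        d = dict(d)
        d["encoder_hidden"] = tuple(d["encoder_hidden"])
        d["disc_hidden"] = tuple(d["disc_hidden"])
        return cls(**d)


class AAEModel:
    """Encoder/decoder/discriminator plus three independent RMSprop states."""

    def __init__(self, config: AAEConfig):
        if config.input_dim <= 0:
            raise ValueError("input_dim must be set to the number of input genes")
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc_dims = [config.input_dim, *config.encoder_hidden, config.latent_dim]
        dec_dims = enc_dims[::-1]
        disc_dims = [config.latent_dim, *config.disc_hidden, 1]
        self.encoder = MLP(enc_dims, "leaky_relu", config.encoder_final, config.leaky_slope, rng)
        self.decoder = MLP(dec_dims, "leaky_relu", config.decoder_final, config.leaky_slope, rng)
        self.discriminator = MLP(disc_dims, "leaky_relu", config.disc_final, config.leaky_slope, rng)
        lr = config.learning_rate
        self.opt_rec = RMSprop(lr)    # encoder + decoder, reconstruction path
        self.opt_gen = RMSprop(lr)    # encoder, generator path
        self.opt_disc = RMSprop(lr)   # discriminator

    # -- plain maps -------------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.predict(np.atleast_2d(np.asarray(x, dtype=float)))

    def decode(self, z: np.ndarray) -> np.ndarray:
        out = self.decoder.predict(np.atleast_2d(np.asarray(z, dtype=float)))
        if self.config.decoder_final == "relu":
            out = np.clip(out, 0.0, 1.0)
        return out

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(x))

    # -- one adversarial training step ------------------------------------
    def adversarial_step(
        self, x_b: np.ndarray, prior_recon: np.ndarray | None = None
    ) -> tuple[StepLosses, np.ndarray]:
        """Update all three networks on one batch; return losses and x'_b.

        The returned reconstruction of the current batch becomes the next
        step's ``prior_recon``; on the first step (no prior) the current
        batch's own reconstruction, computed without gradients, stands in.
        """
        x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
        if x_b.shape[0] == 0:
            raise ValueError("empty batch")
        if prior_recon is None:
            prior_recon = self.reconstruct(x_b)

        n = x_b.size
        # 1) autoencoder on the reconstruction loss
        z_b, enc_cache = self.encoder.forward(x_b)
        x_prime, dec_cache = self.decoder.forward(z_b)
        L_rec = reconstruction_loss(x_b, x_prime)
        xp_c = np.clip(x_prime, EPS, 1.0 - EPS)
        g_out = (-(x_b / xp_c) + (1.0 - x_b) / (1.0 - xp_c)) / n
        g_out *= (x_prime > EPS) & (x_prime < 1.0 - EPS)
        dec_grads, g_z = self.decoder.backward(g_out, dec_cache)
        enc_grads, _ = self.encoder.backward(g_z, enc_cache)
        self.opt_rec.update(
            self.encoder.params() + self.decoder.params(), enc_grads + dec_grads
        )

        # 2) generator path: encoder re-encodes the prior reconstruction
        n_r, enc_cache2 = self.encoder.forward(prior_recon)
        d_fake, disc_cache = self.discriminator.forward(n_r)
        L_gen = generator_loss(d_fake, self.config.gen_loss_mode)
        df_c = np.clip(d_fake, EPS, 1.0 - EPS)
        m = d_fake.shape[0]
        if self.config.gen_loss_mode == "paper":
            g_d = (1.0 / (1.0 - df_c)) / m
        else:
            g_d = (-1.0 / df_c) / m
        g_d = g_d * ((d_fake > EPS) & (d_fake < 1.0 - EPS))
        _, g_nr = self.discriminator.backward(g_d, disc_cache)
        enc_grads2, _ = self.encoder.backward(g_nr, enc_cache2)
        self.opt_gen.update(self.encoder.params(), enc_grads2)

        # 3) discriminator on authentic vs simulated latents (current weights);
        # the prior batch may be shorter (last incomplete batch of an epoch),
        # so both sides are truncated to the common length
        k = min(x_b.shape[0], prior_recon.shape[0])
        z_b2 = self.encoder.predict(x_b[:k])
        n_r2 = self.encoder.predict(prior_recon[:k])
        d_real, cache_r = self.discriminator.forward(z_b2)
        d_fake2, cache_f = self.discriminator.forward(n_r2)
        L_disc = discriminator_loss(d_real, d_fake2)
        dr_c = np.clip(d_real, EPS, 1.0 - EPS)
        df2_c = np.clip(d_fake2, EPS, 1.0 - EPS)
        g_r = (-1.0 / dr_c) / k * ((d_real > EPS) & (d_real < 1.0 - EPS))
        g_f = (1.0 / (1.0 - df2_c)) / k * ((d_fake2 > EPS) & (d_fake2 < 1.0 - EPS))
        grads_r, _ = self.discriminator.backward(g_r, cache_r)
        grads_f, _ = self.discriminator.backward(g_f, cache_f)
        disc_grads = [a + b for a, b in zip(grads_r, grads_f)]
        self.opt_disc.update(self.discriminator.params(), disc_grads)

        losses = StepLosses(L_rec=L_rec, L_gen=L_gen, L_disc=L_disc)
        losses.check_finite()
        x_prime_out = x_prime
        if self.config.decoder_final == "relu":
            x_prime_out = np.clip(x_prime_out, 0.0, 1.0)
        return losses, x_prime_out

    # -- full-matrix reconstruction ---------------------------------------
    def reconstruct_full(self, values: np.ndarray, batch_size: int) -> np.ndarray:
        """Reconstruct every cell batch by batch, preserving row order."""
        values = np.asarray(values, dtype=float)
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        out = [
            self.reconstruct(values[i : i + batch_size])
            for i in range(0, values.shape[0], batch_size)
        ]
        return np.vstack(out)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        import json

        arrays: dict[str, np.ndarray] = {}
        for name, net in (
            ("enc", self.encoder),
            ("dec", self.decoder),
            ("disc", self.discriminator),
        ):
            for i, (W, b) in enumerate(zip(net.W, net.b)):
                arrays[f"{name}_W{i}"] = W
                arrays[f"{name}_b{i}"] = b
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AAEModel":
        import json

        with np.load(Path(path)) as data:
            config = AAEConfig.from_dict(
                json.loads(bytes(data["config_json"]).decode())
            )
            model = cls(config)
            for name, net in (
                ("enc", model.encoder),
                ("dec", model.decoder),
                ("disc", model.discriminator),
            ):
                for i in range(len(net.W)):
                    net.W[i] = data[f"{name}_W{i}"].copy()
                    net.b[i] = data[f"{name}_b{i}"].copy()
        return model


def train(
    model: AAEModel,
    values: np.ndarray,
    batch_size: int,
    epochs: int,
    *,
    seed: int = 0,
    shuffle: bool = True,
    early_stop_patience: int | None = None,
    early_stop_tol: float = 1e-5,
) -> list[StepLosses]:
    """Adversarial training over whole epochs; returns the step-loss trajectory.

    The last incomplete batch of each epoch is kept so every cell contributes.
    With ``early_stop_patience`` set, training stops once the epoch-mean
    reconstruction loss has not improved by ``early_stop_tol`` for that many
    epochs.
    """
    values = np.asarray(values, dtype=float)
    n_cells = values.shape[0]
    batch_size = min(max(1, batch_size), n_cells)
    rng = np.random.default_rng(seed)
    trajectory: list[StepLosses] = []
    prior_recon = None
    best = np.inf
    stale = 0
    for _ in range(epochs):
        order = rng.permutation(n_cells) if shuffle else np.arange(n_cells)
        epoch_rec = []
        for start in range(0, n_cells, batch_size):
            batch = values[order[start : start + batch_size]]
            losses, recon = model.adversarial_step(batch, prior_recon)
            prior_recon = recon
            trajectory.append(losses)
            epoch_rec.append(losses.L_rec)
        if early_stop_patience is not None:
            mean_rec = float(np.mean(epoch_rec))
            if mean_rec < best - early_stop_tol:
                best = mean_rec
                stale = 0
            else:
                stale += 1
                if stale >= early_stop_patience:
                    break
    return trajectory
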