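"""Shipped configuration presets.

``fig2_preset`` (in :mod:`dbaae.simulate`) fixes the simulated benchmark
layout: 200 genes, 2/6/8 groups, dropout on or off.  The model presets here
pair it with network sizes: ``published_model`` uses the published
architecture (input-1024-512-512 encoder, 512-256-1 discriminator, RMSprop at
2e-5), while ``scaled_model`` is a proportionally shrunk configuration for
few-hundred-cell runs, where the small step count makes a faster learning
rate appropriate.
"""

from __future__ import annotations

from .aae import AAEConfig


def published_model(input_dim: int, seed: int = 0) -> AAEConfig:
    """The published architecture and optimizer settings."""
    return AAEConfig(
        input_dim=input_dim,
        encoder_hidden=(1024, 512),
        latent_dim=512,
        disc_hidden=(256,),
        learning_rate=2e-5,
        seed=seed,
    )


def scaled_model(input_dim: int = 200, seed: int = 0) -> AAEConfig:
    """Shrunk architecture for small (hundreds of cells) simulated runs.

    Mirrors the published shape — two hidden encoder layers with the latent
    width equal to the second, discriminator half the latent width — at
    roughly an eighth of the size, with the learning rate raised to 1e-3 so
    training converges within a few hundred epochs at these problem sizes.
    """
    return AAEConfig(
        input_dim=input_dim,
        encoder_hidden=(128, 64),
        latent_dim=64,
        disc_hidden=(32,),
        learning_rate=1e-3,
        seed=seed,
    )
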