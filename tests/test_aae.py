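"""AAE core: loss oracles, network forward passes, training-step contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbaae.aae import (
    EPS,
    AAEConfig,
    AAEModel,
    MLP,
    discriminator_loss,
    generator_loss,
    reconstruction_loss,
    train,
)

# ---------------------------------------------------------------------------
# independent scalar-loop oracles


def bce_oracle(x, xp):
    total, n = 0.0, 0
    for xi, pi in zip(np.ravel(x), np.ravel(xp)):
        pi = min(max(pi, EPS), 1.0 - EPS)
        total += xi * math.log(pi) + (1.0 - xi) * math.log(1.0 - pi)
        n += 1
    return -total / n


def gen_oracle(d_fake, mode="paper"):
    total = 0.0
    for d in np.ravel(d_fake):
        d = min(max(d, EPS), 1.0 - EPS)
        total += math.log(1.0 - d) if mode == "paper" else math.log(d)
    return -total / np.size(d_fake)


def disc_oracle(d_real, d_fake):
    total = 0.0
    for dr, df in zip(np.ravel(d_real), np.ravel(d_fake)):
        dr = min(max(dr, EPS), 1.0 - EPS)
        df = min(max(df, EPS), 1.0 - EPS)
        total += math.log(dr) + math.log(1.0 - df)
    return -total / np.size(d_real)


def mlp_oracle(net, x):
    """Per-element re-implementation of the dense stack."""
    out = np.empty((x.shape[0], net.out_dim))
    for r in range(x.shape[0]):
        h = list(x[r])
        for W, b, act in zip(net.W, net.b, net.activations):
            nxt = []
            for j in range(W.shape[1]):
                a = b[j] + sum(h[i] * W[i, j] for i in range(W.shape[0]))
                if act == "leaky_relu":
                    nxt.append(a if a > 0 else net.leaky_slope * a)
                elif act == "relu":
                    nxt.append(max(a, 0.0))
                elif act == "sigmoid":
                    nxt.append(1.0 / (1.0 + math.exp(-a)))
                else:
                    nxt.append(a)
            h = nxt
        out[r] = h
    return out


unit_vectors = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20).map(np.array)


class TestLossOracles:
    @settings(deadline=None, derandomize=True, max_examples=120)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=30
        )
    )
    def test_reconstruction_loss_matches_scalar_loop(self, pairs):
        x = np.array([p[0] for p in pairs])
        xp = np.array([p[1] for p in pairs])
        assert reconstruction_loss(x, xp) == pytest.approx(
            bce_oracle(x, xp), abs=1e-9
        )

    @settings(deadline=None, derandomize=True, max_examples=120)
    @given(unit_vectors, st.sampled_from(["paper", "nonsaturating"]))
    def test_generator_loss_matches_scalar_loop(self, d, mode):
        assert generator_loss(d, mode) == pytest.approx(gen_oracle(d, mode), abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=120)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=30))
    def test_discriminator_loss_matches_scalar_loop(self, pairs):
        dr = np.array([p[0] for p in pairs])
        df = np.array([p[1] for p in pairs])
        assert discriminator_loss(dr, df) == pytest.approx(
            disc_oracle(dr, df), abs=1e-9
        )


class TestLossCheckpoints:
    def test_bce_half_reconstruction(self):
        assert reconstruction_loss(
            np.array([1.0, 0.0]), np.array([0.5, 0.5])
        ) == pytest.approx(0.693147, abs=1e-6)

    def test_bce_perfect_binary(self):
        assert reconstruction_loss(
            np.array([1.0, 0.0]), np.array([1.0, 0.0])
        ) == pytest.approx(0.0, abs=1e-6)

    def test_generator_checkpoints(self):
        assert generator_loss(np.array([0.5, 0.5])) == pytest.approx(0.693147, abs=1e-6)
        assert generator_loss(np.array([0.0, 0.0])) == pytest.approx(0.0, abs=1e-6)

    def test_discriminator_checkpoints(self):
        half = np.array([0.5, 0.5])
        assert discriminator_loss(half, half) == pytest.approx(1.386294, abs=1e-6)
        perfect = discriminator_loss(np.array([1.0]), np.array([0.0]))
        assert perfect == pytest.approx(0.0, abs=1e-6)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            generator_loss(np.array([1.5]))
        with pytest.raises(ValueError):
            discriminator_loss(np.array([0.5]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros(3), np.zeros(4))


class TestNetworks:
    def test_zero_weights_give_zero_latent(self, tiny_model_config):
        model = AAEModel(tiny_model_config)
        for i in range(len(model.encoder.W)):
            model.encoder.W[i][:] = 0.0
        x = np.random.default_rng(0).uniform(size=(4, 20))
        assert np.allclose(model.encode(x), 0.0)

    def test_single_layer_hand_case(self):
        rng = np.random.default_rng(0)
        net = MLP([2, 1], "leaky_relu", "leaky_relu", 0.2, rng)
        net.W[0] = np.array([[1.0], [1.0]])
        net.b[0] = np.zeros(1)
        assert net.predict(np.array([[1.0, -1.0]]))[0, 0] == 0.0

    def test_encoder_matches_scalar_loop(self, tiny_model_config, rng):
        model = AAEModel(tiny_model_config)
        x = rng.uniform(size=(3, 20))
        assert np.allclose(model.encode(x), mlp_oracle(model.encoder, x), atol=1e-6)

    def test_decoder_matches_scalar_loop(self, tiny_model_config, rng):
        model = AAEModel(tiny_model_config)
        z = rng.normal(size=(3, 8))
        assert np.allclose(model.decode(z), mlp_oracle(model.decoder, z), atol=1e-6)

    def test_decoder_zero_latent_sigmoid_center(self, tiny_model_config):
        model = AAEModel(tiny_model_config)
        for i in range(len(model.decoder.W)):
            model.decoder.W[i][:] = 0.0
        out = model.decode(np.zeros((1, 8)))
        assert np.allclose(out, 0.5)

    def test_decoder_mirrors_encoder(self, tiny_model_config):
        model = AAEModel(tiny_model_config)
        assert model.decoder.dims == model.encoder.dims[::-1]
        assert model.discriminator.in_dim == model.config.latent_dim

    def test_width_mismatch_raises(self, tiny_model_config):
        model = AAEModel(tiny_model_config)
        with pytest.raises(ValueError, match="width"):
            model.encode(np.zeros((2, 7)))
        with pytest.raises(ValueError, match="width"):
            model.decode(np.zeros((2, 7)))


class TestAdversarialStep:
    def test_zero_learning_rate_freezes_weights(self, tiny_model_config, rng):
        config = AAEConfig(**{**tiny_model_config.to_dict(), "learning_rate": 0.0})
        model = AAEModel(config)
        before = [W.copy() for W in model.encoder.W + model.decoder.W + model.discriminator.W]
        losses, recon = model.adversarial_step(rng.uniform(size=(10, 20)))
        after = model.encoder.W + model.decoder.W + model.discriminator.W
        for b, a in zip(before, after):
            assert np.array_equal(b, a)
        assert np.isfinite([losses.L_rec, losses.L_gen, losses.L_disc]).all()
        assert losses.a_loss == losses.L_gen + losses.L_disc

    def test_fixed_seed_identical_loss_sequence(self, tiny_model_config, rng):
        x = rng.uniform(size=(30, 20))
        seqs = []
        for _ in range(2):
            model = AAEModel(tiny_model_config)
            traj = train(model, x, batch_size=8, epochs=3, seed=5)
            seqs.append([(s.L_rec, s.L_gen, s.L_disc) for s in traj])
        assert seqs[0] == seqs[1]

    def test_reconstruction_step_descends(self, tiny_model_config, rng):
        """A tiny reconstruction-only update strictly decreases L_rec."""
        config = AAEConfig(**{**tiny_model_config.to_dict(), "learning_rate": 1e-5})
        model = AAEModel(config)
        model.opt_gen.lr = 0.0
        model.opt_disc.lr = 0.0
        x = rng.uniform(size=(16, 20))
        before = reconstruction_loss(x, model.reconstruct(x))
        model.adversarial_step(x)
        after = reconstruction_loss(x, model.reconstruct(x))
        assert after < before

    def test_training_reduces_reconstruction_loss(self, toy_normalized):
        config = AAEConfig(
            input_dim=toy_normalized.n_genes,
            encoder_hidden=(16,),
            latent_dim=8,
            disc_hidden=(8,),
            learning_rate=1e-3,
            seed=0,
        )
        model = AAEModel(config)
        traj = train(model, toy_normalized.values, batch_size=10, epochs=20, seed=0)
        assert traj[-1].L_rec < traj[0].L_rec

    def test_empty_batch_rejected(self, tiny_model_config):
        model = AAEModel(tiny_model_config)
        with pytest.raises(ValueError):
            model.adversarial_step(np.empty((0, 20)))


class TestReconstructFull:
    def test_partition_invariance(self, tiny_model_config, rng):
        model = AAEModel(tiny_model_config)
        x = rng.uniform(size=(25, 20))
        full = model.reconstruct_full(x, batch_size=25)
        for bs in (1, 4, 7, 25, 40):
            assert np.abs(model.reconstruct_full(x, bs) - full).max() <= 1e-6

    def test_rows_match_standalone_reconstruction(self, tiny_model_config, rng):
        model = AAEModel(tiny_model_config)
        x = rng.uniform(size=(9, 20))
        out = model.reconstruct_full(x, batch_size=4)
        for i in range(9):
            row = model.decode(model.encode(x[i : i + 1]))
            assert np.allclose(out[i], row[0], atol=1e-9)

    def test_output_in_unit_interval(self, tiny_model_config, rng):
        model = AAEModel(tiny_model_config)
        out = model.reconstruct_full(rng.uniform(size=(12, 20)), batch_size=5)
        assert out.shape == (12, 20)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model_config, tmp_path, rng):
        model = AAEModel(tiny_model_config)
        train(model, rng.uniform(size=(20, 20)), batch_size=5, epochs=2, seed=1)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = AAEModel.load(path)
        x = rng.uniform(size=(6, 20))
        assert np.array_equal(model.reconstruct(x), loaded.reconstruct(x))
        assert loaded.config == model.config
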