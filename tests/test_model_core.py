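"""Architecture wiring: latent bridging, attention, variational head,
decoding contracts and checkpoint persistence."""

import numpy as np
import pytest

from molae.autodiff import Tensor, masked_softmax
from molae.chemio import Vocabulary, one_hot_encode, tokenize_smiles
from molae.model_core import (
    LatentMatrix,
    ModelConfig,
    MoleculeAutoencoder,
    kl_divergence,
    reparameterize,
)
from molae.nn import AdditiveAttention
from molae.training import _batch_loss_graph

VOCAB = Vocabulary(("<pad>", "<sos>", "<eos>", "(", ")", "1", "=", "C", "N", "O"))


def batch_of(strings, max_len=10):
    return one_hot_encode([tokenize_smiles(s) for s in strings], VOCAB, max_len)


class TestLatentBridge:
    def test_gru_base_has_no_bridge_and_z_is_h_T(self):
        """With one GRU layer and hidden == latent, the latent vector IS
        the final hidden state — bitwise, with zero bridge parameters."""
        model = MoleculeAutoencoder(ModelConfig("gru", 64, 64, 1), VOCAB, seed=0)
        assert model.bridge_parameter_count == 0
        batch = batch_of(["CCO", "C=NC", "CC(N)=O"])
        z = model.encode(batch)
        state = model.encoder_state(batch)
        assert np.array_equal(z.values, state.h_T[0])

    def test_gru_reduced_latent_has_exactly_one_projection(self):
        model = MoleculeAutoencoder(ModelConfig("gru", 64, 32, 1), VOCAB, seed=0)
        assert model.latent_proj is not None
        assert model.latent_proj.W.shape == (64, 32)
        # encoder-side projection plus the matching decoder-init map
        assert model.bridge_parameter_count == (64 * 32 + 32) + (32 * 64 + 64)

    def test_lstm_bridge_consumes_hidden_and_cell_state(self):
        model = MoleculeAutoencoder(ModelConfig("lstm", 64, 64, 1), VOCAB, seed=0)
        assert model.latent_proj.W.shape == (2 * 64, 64)
        state = model.encoder_state(batch_of(["CCO"]))
        assert state.c_T is not None and state.h_T[0].shape == (1, 64)

    def test_gru_state_has_no_cell_component(self):
        state = MoleculeAutoencoder(
            ModelConfig("gru", 16, 16, 2), VOCAB, seed=0
        ).encoder_state(batch_of(["CCO"]))
        assert state.c_T is None and len(state.h_T) == 2

    def test_attention_forces_projection(self):
        model = MoleculeAutoencoder(
            ModelConfig("gru", 64, 64, 1, attention=True), VOCAB, seed=0
        )
        assert model.latent_proj is not None
        assert model.latent_proj.W.shape == (128, 64)  # h_T ⊕ context

    def test_multilayer_concatenates_all_final_states(self):
        model = MoleculeAutoencoder(ModelConfig("lstm", 16, 8, 3), VOCAB, seed=0)
        assert model.latent_proj.W.shape == (2 * 16 * 3, 8)

    def test_padding_does_not_change_the_latent(self):
        model = MoleculeAutoencoder(ModelConfig("gru", 32, 32, 1), VOCAB, seed=1)
        z_short = model.encode(batch_of(["CCO", "CN"], max_len=5)).values
        z_long = model.encode(batch_of(["CCO", "CN"], max_len=9)).values
        assert np.allclose(z_short, z_long)


class TestAttention:
    def test_single_step_context_equals_that_step(self):
        rng = np.random.default_rng(0)
        att = AdditiveAttention(6, rng)
        step = Tensor(rng.standard_normal((3, 6)))
        w = masked_softmax(att.scores([step]), np.ones((3, 1)))
        assert np.allclose(w.data, 1.0)

    def test_identical_steps_share_weight_equally(self):
        rng = np.random.default_rng(0)
        att = AdditiveAttention(6, rng)
        step = Tensor(rng.standard_normal((2, 6)))
        w = masked_softmax(att.scores([step, step]), np.ones((2, 2)))
        assert np.allclose(w.data, 0.5)


class TestDecoding:
    def test_step_probabilities_sum_to_one(self):
        model = MoleculeAutoencoder(ModelConfig("gru", 16, 16, 1), VOCAB, seed=2)
        z = model.encode(batch_of(["CCO", "CC(N)=O"]))
        probs, _ = model.greedy_decode(z, max_len=8)
        sums = probs.sum(axis=2)
        assert np.allclose(sums[sums > 0], 1.0)

    def test_immediate_eos_gives_empty_reconstruction(self):
        model = MoleculeAutoencoder(ModelConfig("gru", 16, 16, 1), VOCAB, seed=2)
        model.output.b.data[:] = 0.0
        model.output.W.data[:] = 0.0
        model.output.b.data[VOCAB.eos_index] = 10.0
        _, strings = model.greedy_decode(np.zeros((2, 16)), max_len=8)
        assert strings == ["", ""]

    def test_greedy_decode_is_deterministic(self):
        model = MoleculeAutoencoder(ModelConfig("lstm", 16, 12, 2), VOCAB, seed=3)
        z = model.encode(batch_of(["CCO", "C1CC1"]))
        a = model.greedy_decode(z, max_len=8)[1]
        b = model.greedy_decode(z, max_len=8)[1]
        assert a == b

    def test_teacher_forced_probabilities_shape(self):
        model = MoleculeAutoencoder(ModelConfig("gru", 16, 16, 1), VOCAB, seed=2)
        batch = batch_of(["CCO", "CN"], max_len=6)
        z = model.encode(batch)
        probs, strings = model.decode(z, max_len=6, teacher=batch)
        assert probs.shape == (2, 6, len(VOCAB))
        assert len(strings) == 2

    def test_latent_width_mismatch_rejected(self):
        model = MoleculeAutoencoder(ModelConfig("gru", 16, 16, 1), VOCAB, seed=2)
        with pytest.raises(ValueError):
            model.greedy_decode(np.zeros((2, 9)), max_len=5)
        with pytest.raises(ValueError):
            LatentMatrix(np.zeros((2, 9)), model.config)


class TestVariational:
    def test_kl_closed_forms(self):
        assert kl_divergence(np.zeros(4), np.zeros(4)) == 0.0
        assert kl_divergence(np.array([1.0, 0.0]), np.zeros(2)) == pytest.approx(0.5)

    def test_reparameterize_mean_limit(self):
        mu = np.array([[1.0, -2.0]])
        z = reparameterize(mu, np.full((1, 2), -60.0), seed=0)  # sd ~ e^-30
        assert np.allclose(z, mu)

    def test_reparameterize_seeded(self):
        mu, logvar = np.zeros((3, 4)), np.zeros((3, 4))
        assert np.array_equal(
            reparameterize(mu, logvar, 7), reparameterize(mu, logvar, 7)
        )

    def test_encode_returns_mean_deterministically(self):
        model = MoleculeAutoencoder(
            ModelConfig("gru", 12, 8, 1, variational=True), VOCAB, seed=4
        )
        batch = batch_of(["CCO", "CN"])
        assert np.array_equal(model.encode(batch).values, model.encode(batch).values)

    def test_beta_zero_eps_zero_reduces_to_plain_autoencoder(self):
        """With shared weights, no sampling and no KL weight, the
        variational model's loss equals the plain autoencoder's."""
        plain = MoleculeAutoencoder(ModelConfig("gru", 12, 8, 1), VOCAB, seed=5)
        var = MoleculeAutoencoder(
            ModelConfig("gru", 12, 8, 1, variational=True, kl_weight=0.0),
            VOCAB, seed=5,
        )
        plain_params = dict(plain.parameters())
        for name, p in var.parameters():
            source = name.replace("mu_head", "latent_proj")
            if source in plain_params:
                p.data = plain_params[source].data.copy()
        batch = batch_of(["CCO", "CC(N)=O", "C1CC1"])
        loss_plain, _, _ = _batch_loss_graph(plain, batch, batch, None)
        loss_var, _, _ = _batch_loss_graph(var, batch, batch, None)
        assert float(loss_var.data) == pytest.approx(float(loss_plain.data), abs=1e-12)


class TestPersistence:
    def test_save_load_bit_exact(self, tmp_path):
        model = MoleculeAutoencoder(
            ModelConfig("lstm", 12, 8, 2, attention=True), VOCAB, seed=6
        )
        model.save(tmp_path / "ckpt")
        loaded = MoleculeAutoencoder.load(tmp_path / "ckpt")
        for (name_a, a), (name_b, b) in zip(model.parameters(), loaded.parameters()):
            assert name_a == name_b
            assert np.array_equal(a.data, b.data)
        batch = batch_of(["CCO", "C1CC1N"])
        assert np.array_equal(model.encode(batch).values, loaded.encode(batch).values)

    def test_vocab_mismatch_rejected(self):
        model = MoleculeAutoencoder(ModelConfig("gru", 8, 8, 1), VOCAB, seed=0)
        other = Vocabulary(("<pad>", "<sos>", "<eos>", "C"))
        bad = one_hot_encode([tokenize_smiles("CC")], other, 4)
        with pytest.raises(ValueError, match="vocab"):
            model.encode(bad)
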