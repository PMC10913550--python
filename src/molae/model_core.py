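"""The recurrent molecule-autoencoder architecture family.

A molecule string enters as a one-hot token sequence, is read by a GRU or
LSTM encoder (1-3 layers, optional additive attention), is compressed into
a latent vector ``z``, and is reconstructed token-by-token by a matching
recurrent decoder (teacher-forced during training, greedy otherwise).

Latent bridging follows the reference wiring exactly:

* GRU, one layer, hidden size == latent size, no attention, non-variational:
  ``z`` *is* the final hidden state ``h_T`` — the bridge has no parameters.
* Any other GRU: ``z = Linear(concat of per-layer h_T)``.
* LSTM: the final hidden and cell states of all layers are concatenated and
  projected, ``z = Linear(h_T ⊕ c_T)``; the decoder's initial hidden and
  cell states come from two separate linear maps of ``z``.
* Attention on: the attention context vector is concatenated to the final
  states before the projection (which then always exists).
* Variational: two linear heads give ``mu`` and ``log sigma^2``;
  ``encode`` returns the mean, sampling happens only in training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, cross_entropy_logits, masked_softmax, softmax
from .chemio import OneHotBatch, Vocabulary, decode_indices
from .nn import AdditiveAttention, GRULayer, Linear, LSTMLayer, Module

GRU = "gru"
LSTM = "lstm"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The reference base configuration is one layer, hidden and latent size
    64, no attention, non-variational — sized so the hidden state exceeds
    the maximum sequence length of typical drug-like corpora.
    """

    cell: str = GRU
    hidden_size: int = 64
    latent_size: int = 64
    num_layers: int = 1
    attention: bool = False
    variational: bool = False
    kl_weight: float = 0.3

    def __post_init__(self) -> None:
        if self.cell not in (GRU, LSTM):
            raise ValueError(f"cell must be one of {GRU!r}, {LSTM!r}; got {self.cell!r}")
        if self.num_layers not in (1, 2, 3):
            raise ValueError("num_layers must be 1, 2 or 3")
        if self.hidden_size < 1 or self.latent_size < 1:
            raise ValueError("hidden_size and latent_size must be positive")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be non-negative")


@dataclass
class LatentMatrix:
    """``[n_molecules, latent_size]`` encoder output."""

    values: np.ndarray
    config: ModelConfig

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != self.config.latent_size:
            raise ValueError("latent matrix shape does not match config")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite latent values")


@dataclass
class EncoderState:
    """Final recurrent states: one ``h_T`` per layer, plus ``c_T`` for LSTMs."""

    h_T: list[np.ndarray]
    c_T: list[np.ndarray] | None = None


def reparameterize(
    mu: np.ndarray, logvar: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``z = mu + exp(logvar/2) * eps`` with standard-normal ``eps``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(np.shape(mu))
    return np.asarray(mu) + np.exp(np.asarray(logvar) / 2.0) * eps


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Diagonal-Gaussian KL to the standard normal,
    ``-1/2 * sum(1 + logvar - mu^2 - exp(logvar))`` per sample; for a 2-D
    batch the per-sample sums are averaged."""
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    per_elem = -0.5 * (1.0 + logvar - mu**2 - np.exp(logvar))
    if per_elem.ndim <= 1:
        return float(per_elem.sum())
    return float(per_elem.sum(axis=1).mean())


class MoleculeAutoencoder(Module):
    """A configurable GRU/LSTM (optionally variational) string autoencoder.

    Construct from a :class:`ModelConfig` and the corpus
    :class:`~molae.chemio.Vocabulary`; fit with
    :func:`molae.training.train` or the :meth:`fit` convenience wrapper.
    """

    def __init__(self, config: ModelConfig, vocab: Vocabulary, seed: int = 0):
        self.config = config
        self.vocab = vocab
        self.seed = seed
        rng = np.random.default_rng(seed)
        V, H, L, m = len(vocab), config.hidden_size, config.latent_size, config.num_layers
        cell_cls = GRULayer if config.cell == GRU else LSTMLayer

        self.encoder_layers = [
            cell_cls(V if l == 0 else H, H, rng, name=f"enc.{l}") for l in range(m)
        ]
        self.attention = AdditiveAttention(H, rng) if config.attention else None

        state_width = H * m * (2 if config.cell == LSTM else 1)
        feature_width = state_width + (H if config.attention else 0)
        self._identity_bridge = (
            config.cell == GRU
            and m == 1
            and H == L
            and not config.attention
            and not config.variational
        )
        self.latent_proj: Linear | None = None
        self.mu_head: Linear | None = None
        self.logvar_head: Linear | None = None
        if config.variational:
            self.mu_head = Linear(feature_width, L, rng, name="mu_head")
            self.logvar_head = Linear(feature_width, L, rng, name="logvar_head")
        elif not self._identity_bridge:
            self.latent_proj = Linear(feature_width, L, rng, name="latent_proj")

        self._identity_dec_init = m == 1 and H == L
        self.dec_init_h: Linear | None = None
        self.dec_init_c: Linear | None = None
        if config.cell == GRU:
            if not self._identity_dec_init:
                self.dec_init_h = Linear(L, H * m, rng, name="dec_init_h")
        else:
            self.dec_init_h = Linear(L, H * m, rng, name="dec_init_h")
            self.dec_init_c = Linear(L, H * m, rng, name="dec_init_c")

        self.decoder_layers = [
            cell_cls(V if l == 0 else H, H, rng, name=f"dec.{l}") for l in range(m)
        ]
        self.output = Linear(H, V, rng, name="output")

    # -- parameters --------------------------------------------------------

    def parameters(self):
        params: list[tuple[str, Tensor]] = []
        for layer in self.encoder_layers:
            params += layer.parameters()
        if self.attention is not None:
            params += self.attention.parameters()
        for head in (self.latent_proj, self.mu_head, self.logvar_head,
                     self.dec_init_h, self.dec_init_c):
            if head is not None:
                params += head.parameters()
        for layer in self.decoder_layers:
            params += layer.parameters()
        params += self.output.parameters()
        return params

    @property
    def bridge_parameter_count(self) -> int:
        """Parameters of the encoder->latent->decoder bridge only."""
        total = 0
        for head in (self.latent_proj, self.mu_head, self.logvar_head,
                     self.dec_init_h, self.dec_init_c):
            if head is not None:
                total += sum(int(np.prod(p.shape)) for _, p in head.parameters())
        return total

    # -- encoder -----------------------------------------------------------

    def _check_batch(self, batch: OneHotBatch) -> None:
        if batch.array.shape[2] != len(self.vocab):
            raise ValueError(
                f"batch vocab size {batch.array.shape[2]} != model vocab {len(self.vocab)}"
            )

    def _run_encoder(self, batch: OneHotBatch):
        """Returns (per-layer final h, per-layer final c or None, top-layer
        step outputs, step mask)."""
        self._check_batch(batch)
        B, T, _ = batch.array.shape
        H = self.config.hidden_size
        step_mask = (np.arange(T)[None, :] < batch.lengths[:, None]).astype(np.float64)
        outs = [Tensor(batch.array[:, t, :]) for t in range(T)]
        final_h: list[Tensor] = []
        final_c: list[Tensor] = []
        for layer in self.encoder_layers:
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            new_outs = []
            for t in range(T):
                m = Tensor(step_mask[:, t : t + 1])
                if self.config.cell == GRU:
                    h_new = layer.step(outs[t], h)
                else:
                    h_new, c_new = layer.step(outs[t], h, c)
                    c = m * c_new + (1.0 - m) * c
                h = m * h_new + (1.0 - m) * h
                new_outs.append(h)
            outs = new_outs
            final_h.append(h)
            final_c.append(c)
        return final_h, (final_c if self.config.cell == LSTM else None), outs, step_mask

    def _latent_graph(self, batch: OneHotBatch):
        """Latent tensor graph: (z_feature, mu, logvar); for non-variational
        models mu/logvar are None and z_feature is z itself."""
        final_h, final_c, step_outs, step_mask = self._run_encoder(batch)
        parts = list(final_h)
        if final_c is not None:
            parts += final_c
        if self.attention is not None:
            weights = masked_softmax(self.attention.scores(step_outs), step_mask)
            context = None
            for t, out in enumerate(step_outs):
                term = weights.narrow(t, t + 1) * out
                context = term if context is None else context + term
            parts.append(context)
        feature = parts[0] if len(parts) == 1 else concat(parts)
        if self.config.variational:
            return None, self.mu_head(feature), self.logvar_head(feature)
        z = feature if self._identity_bridge else self.latent_proj(feature)
        return z, None, None

    def encode(self, batch: OneHotBatch) -> LatentMatrix:
        """Deterministic latent representations (the mean, if variational)."""
        z, mu, _ = self._latent_graph(batch)
        values = mu.data if self.config.variational else z.data
        return LatentMatrix(values.copy(), self.config)

    def encoder_state(self, batch: OneHotBatch) -> EncoderState:
        final_h, final_c, _, _ = self._run_encoder(batch)
        return EncoderState(
            [h.data.copy() for h in final_h],
            [c.data.copy() for c in final_c] if final_c is not None else None,
        )

    def attention_context(self, batch: OneHotBatch) -> np.ndarray:
        """The attention pooling vector for a batch (attention models only)."""
        if self.attention is None:
            raise ValueError("model has no attention layer")
        _, _, step_outs, step_mask = self._run_encoder(batch)
        weights = masked_softmax(self.attention.scores(step_outs), step_mask)
        ctx = sum(
            weights.data[:, t : t + 1] * out.data for t, out in enumerate(step_outs)
        )
        return ctx

    # -- decoder -----------------------------------------------------------

    def _initial_decoder_states(self, z: Tensor):
        H, m = self.config.hidden_size, self.config.num_layers
        if self.config.cell == GRU:
            flat_h = z if self._identity_dec_init else self.dec_init_h(z)
            hs = [flat_h.narrow(l * H, (l + 1) * H) for l in range(m)]
            return hs, None
        flat_h = self.dec_init_h(z)
        flat_c = self.dec_init_c(z)
        hs = [flat_h.narrow(l * H, (l + 1) * H) for l in range(m)]
        cs = [flat_c.narrow(l * H, (l + 1) * H) for l in range(m)]
        return hs, cs

    def _decoder_step(self, x: Tensor, hs, cs):
        for l, layer in enumerate(self.decoder_layers):
            if self.config.cell == GRU:
                hs[l] = layer.step(x, hs[l])
            else:
                hs[l], cs[l] = layer.step(x, hs[l], cs[l])
            x = hs[l]
        return self.output(x)

    def _teacher_logits(self, z: Tensor, teacher: OneHotBatch) -> list[Tensor]:
        """Teacher-forced unroll: step t consumes the ground-truth token
        t-1 (SOS at t=0); returns per-step logits."""
        B, T, V = teacher.array.shape
        hs, cs = self._initial_decoder_states(z)
        logits = []
        sos = np.zeros((B, V))
        sos[:, teacher.vocab.sos_index] = 1.0
        for t in range(T):
            x = Tensor(sos if t == 0 else teacher.array[:, t - 1, :])
            logits.append(self._decoder_step(x, hs, cs))
        return logits

    def greedy_decode(
        self, latents: LatentMatrix | np.ndarray, max_len: int
    ) -> tuple[np.ndarray, list[str]]:
        """Free-running greedy decode from latent vectors.

        Step t consumes the argmax of step t-1, starting from SOS; a
        sequence ends at its first EOS (or at ``max_len``). Returns the
        per-step token probabilities ``[n, max_len, vocab]`` and the
        decoded strings.
        """
        values = latents.values if isinstance(latents, LatentMatrix) else latents
        if values.ndim != 2 or values.shape[1] != self.config.latent_size:
            raise ValueError("latent width does not match model config")
        B, V = values.shape[0], len(self.vocab)
        hs, cs = self._initial_decoder_states(Tensor(values))
        probs = np.zeros((B, max_len, V))
        tokens = np.full((B, max_len), self.vocab.pad_index, dtype=np.int64)
        x = np.zeros((B, V))
        x[:, self.vocab.sos_index] = 1.0
        alive = np.ones(B, dtype=bool)
        for t in range(max_len):
            logits = self._decoder_step(Tensor(x), hs, cs)
            p = softmax(logits.data, axis=1)
            probs[:, t, :] = p
            choice = p.argmax(axis=1)
            tokens[alive, t] = choice[alive]
            alive = alive & (choice != self.vocab.eos_index)
            x = np.zeros((B, V))
            x[np.arange(B), choice] = 1.0
            if not alive.any():
                break
        strings = [decode_indices(row, self.vocab) for row in tokens]
        return probs, strings

    def decode(
        self,
        latents: LatentMatrix | np.ndarray,
        max_len: int,
        teacher: OneHotBatch | None = None,
    ) -> tuple[np.ndarray, list[str]]:
        """Per-step token probabilities plus predicted strings.

        With ``teacher`` the unroll is teacher-forced (step t consumes the
        ground-truth token t-1); otherwise greedy free-running.
        """
        if teacher is None:
            return self.greedy_decode(latents, max_len)
        values = latents.values if isinstance(latents, LatentMatrix) else latents
        logits = self._teacher_logits(Tensor(values), teacher)
        probs = np.stack([softmax(t.data, axis=1) for t in logits], axis=1)
        strings = [decode_indices(row, self.vocab) for row in probs.argmax(axis=2)]
        return probs, strings

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {name: p.data for name, p in self.parameters()}
        np.savez(directory / "weights.npz", **arrays)
        meta = {
            "config": asdict(self.config),
            "vocab": list(self.vocab.tokens),
            "seed": self.seed,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "MoleculeAutoencoder":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(
            ModelConfig(**meta["config"]),
            Vocabulary(tuple(meta["vocab"])),
            seed=meta["seed"],
        )
        arrays = np.load(directory / "weights.npz")
        for name, p in model.parameters():
            p.data = arrays[name].astype(np.float64)
        return model


def count_parameters(config: ModelConfig, vocab_size: int) -> int:
    """Exact trainable-parameter count for a configuration."""
    tokens = ("<pad>", "<sos>", "<eos>") + tuple(
        f"[t{i}]" for i in range(vocab_size - 3)
    )
    return MoleculeAutoencoder(config, Vocabulary(tokens), seed=0).n_parameters()
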