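"""Training protocol: enumeration pairing modes, loss, early stopping and
the multi-seed Adam training loop.

The protocol is fixed by the reference procedure: Adam at learning rate
0.005, teacher forcing on every training step, cross-entropy over non-PAD
positions (plus a constant-weight KL term for variational models), early
stopping on validation loss with min-delta 0.01 and patience 5 acting only
between a minimum of 50 and a maximum of 500 epochs, and three seeds per
configuration reported as mean with min/max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import chemio, metrics
from .autodiff import Tensor, cross_entropy_logits
from .chemio import MoleculeRecord, OneHotBatch, TokenSequence, Vocabulary
from .model_core import ModelConfig, MoleculeAutoencoder, kl_divergence

logger = logging.getLogger(__name__)

CAN2CAN = "can2can"
ENUM2CAN = "enum2can"
CAN2ENUM = "can2enum"
ENUM_MODES = (CAN2CAN, ENUM2CAN, CAN2ENUM)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the reference protocol)."""

    learning_rate: float = 0.005
    min_epochs: int = 50
    max_epochs: int = 500
    min_delta: float = 0.01
    patience: int = 5
    seeds: tuple[int, ...] = (0, 1, 2)
    batch_size: int = 128
    enum_mode: str = CAN2CAN
    validation_fraction: float = 0.1
    holdout_validation: bool = True
    representation: str = chemio.SMILES

    def __post_init__(self) -> None:
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must be <= max_epochs")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.enum_mode not in ENUM_MODES:
            raise ValueError(f"enum_mode must be one of {ENUM_MODES}")
        if not self.seeds:
            raise ValueError("at least one seed required")


@dataclass
class TrainHistory:
    """Per-epoch losses of one seed's run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def epochs(self) -> int:
        return len(self.val_loss)


def make_training_pairs(
    records: list[MoleculeRecord],
    enum_mode: str,
    seed: int,
    representation: str = chemio.SMILES,
) -> list[tuple[str, str]]:
    """(input, target) string pairs for one epoch.

    ``can2can`` autoencodes the canonical string; ``enum2can`` maps a
    seeded-sampled enumeration to the canonical form; ``can2enum`` the
    reverse. Enumerations are resampled per call so augmentation varies
    across epochs.
    """
    if enum_mode not in ENUM_MODES:
        raise ValueError(f"enum_mode must be one of {ENUM_MODES}")
    rng = np.random.default_rng(seed)
    pairs = []
    for rec in records:
        can = rec.canonical(representation)
        if enum_mode == CAN2CAN:
            pairs.append((can, can))
            continue
        enums = rec.enums(representation)
        if not enums:
            raise ValueError(
                f"record {rec.canonical_smiles!r} has no {representation} "
                f"enumerations but enum_mode={enum_mode!r}"
            )
        variant = enums[int(rng.integers(len(enums)))]
        pairs.append((variant, can) if enum_mode == ENUM2CAN else (can, variant))
    return pairs


def loss(
    step_probabilities: np.ndarray,
    target_batch: OneHotBatch,
    mu: np.ndarray | None = None,
    logvar: np.ndarray | None = None,
    beta: float = 0.0,
) -> float:
    """Token-level cross-entropy averaged over non-PAD positions, plus
    ``beta * KL`` when the variational terms are given."""
    targets = target_batch.indices
    B, T = targets.shape
    mask = np.arange(T)[None, :] < target_batch.lengths[:, None]
    p = step_probabilities[np.arange(B)[:, None], np.arange(T)[None, :], targets]
    ce = float(-np.log(np.clip(p, 1e-300, None))[mask].mean())
    if mu is None or logvar is None:
        return ce
    return ce + beta * kl_divergence(mu, logvar)


CONTINUE = "continue"
STOP = "stop"


def check_early_stop(val_losses: list[float], config: TrainConfig) -> str:
    """The stopping rule applied to a validation-loss history.

    Never stops before ``min_epochs``; stops once the loss has failed to
    improve on its running best by more than ``min_delta`` for ``patience``
    consecutive epochs; always stops at ``max_epochs``.
    """
    if not val_losses:
        raise ValueError("empty history")
    epoch = len(val_losses)
    if epoch >= config.max_epochs:
        return STOP
    if epoch < config.min_epochs:
        return CONTINUE
    best = val_losses[0]
    wait = 0
    for value in val_losses[1:]:
        if best - value > config.min_delta:
            best = value
            wait = 0
        else:
            wait += 1
    return STOP if wait >= config.patience else CONTINUE


class _Tokenizer:
    """Memoized tokenization of pair strings."""

    def __init__(self, representation: str):
        self.representation = representation
        self._cache: dict[str, TokenSequence] = {}

    def __call__(self, s: str) -> TokenSequence:
        seq = self._cache.get(s)
        if seq is None:
            seq = chemio.tokenize(s, self.representation)
            self._cache[s] = seq
        return seq


def corpus_vocabulary(
    records: list[MoleculeRecord],
    representation: str,
    include_enumerations: bool = False,
    cover_enumerations: bool = True,
) -> Vocabulary:
    """Vocabulary over every string the training protocol may present.

    Even canonical-only training includes the tokens of a few seeded
    enumerations per molecule (``cover_enumerations``): non-canonical
    strings use structural tokens (branches, ring reopenings) that small
    canonical corpora may lack entirely, and a model whose vocabulary
    misses them could never embed enumerated variants for the latent-space
    diagnostics.
    """
    seqs = [chemio.tokenize(r.canonical(representation), representation) for r in records]
    if include_enumerations:
        for r in records:
            seqs += [chemio.tokenize(s, representation) for s in r.enums(representation)]
    elif cover_enumerations:
        from .selfies_codec import SelfiesError, smiles_to_selfies

        for r in records:
            try:
                enums = chemio.enumerate_smiles(r.canonical_smiles, 4, seed=7)
                if representation == chemio.SELFIES:
                    enums = [smiles_to_selfies(s) for s in enums]
            except (chemio.EnumerationError, SelfiesError):
                continue
            seqs += [chemio.tokenize(s, representation) for s in enums]
    return chemio.build_vocabulary(seqs)


def corpus_max_len(
    records: list[MoleculeRecord], representation: str, include_enumerations: bool
) -> int:
    """Longest sequence (in tokens, plus one EOS slot) in the corpus."""
    longest = 0
    for r in records:
        strings = [r.canonical(representation)]
        if include_enumerations:
            strings += r.enums(representation)
        for s in strings:
            longest = max(longest, len(chemio.tokenize(s, representation)))
    return longest + 1


def _batch_loss_graph(
    model: MoleculeAutoencoder,
    input_batch: OneHotBatch,
    target_batch: OneHotBatch,
    eps_rng: np.random.Generator | None,
):
    """(total loss tensor, ce value, kl value) for one teacher-forced batch."""
    z, mu, logvar = model._latent_graph(input_batch)
    kl_val = 0.0
    if model.config.variational:
        if eps_rng is not None:
            eps = eps_rng.standard_normal(mu.shape)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        else:
            z = mu  # deterministic evaluation
        kl_term = ((1.0 + logvar - mu.square() - logvar.exp()) * (-0.5)).sum() / mu.shape[0]
        kl_val = float(kl_term.data)
    logits = model._teacher_logits(z, target_batch)
    targets = target_batch.indices
    T = targets.shape[1]
    mask = (np.arange(T)[None, :] < target_batch.lengths[:, None]).astype(np.float64)
    total = None
    for t, logit_t in enumerate(logits):
        term = cross_entropy_logits(logit_t, targets[:, t], mask[:, t])
        total = term if total is None else total + term
    n_positions = float(mask.sum())
    ce = total / n_positions
    if model.config.variational:
        full = ce + model.config.kl_weight * kl_term
    else:
        full = ce
    return full, float(ce.data), kl_val


@dataclass
class SeedRun:
    """One seed's trained model and history."""

    seed: int
    model: MoleculeAutoencoder
    history: TrainHistory
    report: metrics.ReconstructionReport | None = None


@dataclass
class FitResults:
    """Results of a multi-seed fit: per-seed models, histories, and
    reconstruction metrics aggregated as mean with min/max across seeds."""

    model_config: ModelConfig
    train_config: TrainConfig
    runs: list[SeedRun]
    vocab: Vocabulary
    max_len: int

    @property
    def aggregate(self) -> dict[str, dict]:
        reports = [r.report for r in self.runs if r.report is not None]
        return metrics.aggregate_reports(reports)

    def summary(self) -> str:
        cfg = self.model_config
        lines = [
            "Molecule autoencoder fit",
            "=" * 60,
            f"cell={cfg.cell} hidden={cfg.hidden_size} latent={cfg.latent_size} "
            f"layers={cfg.num_layers} attention={cfg.attention} "
            f"variational={cfg.variational}",
            f"enum_mode={self.train_config.enum_mode} "
            f"representation={self.train_config.representation} "
            f"seeds={list(self.train_config.seeds)}",
            f"vocabulary={len(self.vocab)} tokens, max_len={self.max_len}",
            "-" * 60,
        ]
        for run in self.runs:
            lines.append(
                f"seed {run.seed}: epochs={run.history.epochs} "
                f"final_val_loss={run.history.val_loss[-1]:.4f} "
                f"({run.history.stop_reason})"
            )
        if any(r.report is not None for r in self.runs):
            agg = self.aggregate
            lines.append("-" * 60)
            for key in ("mean_similarity", "levenshtein_similarity",
                        "full_reconstruction_rate"):
                a = agg[key]
                lines.append(
                    f"{key}: mean={a['mean']:.4f} min={a['min']:.4f} max={a['max']:.4f}"
                )
        return "\n".join(lines)


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    records: list[MoleculeRecord],
    evaluate_on: list[MoleculeRecord] | None = None,
) -> FitResults:
    """Train one configuration for each seed in ``train_config.seeds``.

    Teacher forcing is applied on every training step. Each seed gets its
    own validation split, parameter initialization and epoch-level
    enumeration resampling. If ``evaluate_on`` is given, each seed's model
    is scored on those records with free-running greedy decoding.
    """
    if len(records) < 2:
        raise ValueError("corpus must contain at least 2 molecules")
    rep = train_config.representation
    with_enums = train_config.enum_mode != CAN2CAN
    vocab = corpus_vocabulary(records, rep, with_enums)
    max_len = corpus_max_len(records, rep, with_enums)
    tok = _Tokenizer(rep)

    runs = []
    for seed in train_config.seeds:
        runs.append(
            _train_one_seed(model_config, train_config, records, vocab, max_len, tok, seed)
        )
    if evaluate_on is not None:
        for run in runs:
            run.report = metrics.evaluate_model(run.model, evaluate_on, rep)
    return FitResults(model_config, train_config, runs, vocab, max_len)


def _train_one_seed(
    model_config: ModelConfig,
    cfg: TrainConfig,
    records: list[MoleculeRecord],
    vocab: Vocabulary,
    max_len: int,
    tok: _Tokenizer,
    seed: int,
) -> SeedRun:
    from .nn import Adam

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_val = max(1, int(round(cfg.validation_fraction * len(records))))
    if n_val >= len(records):
        raise ValueError("validation split would consume the whole corpus")
    val_records = [records[i] for i in order[:n_val]]
    # memorization-style runs monitor a subset without holding it out
    train_records = (
        [records[i] for i in order[n_val:]] if cfg.holdout_validation else list(records)
    )

    model = MoleculeAutoencoder(model_config, vocab, seed=seed)
    optimizer = Adam([p for _, p in model.parameters()], lr=cfg.learning_rate)
    history = TrainHistory()
    # fixed validation pairing so the early-stopping signal is comparable
    # across epochs
    val_pairs = make_training_pairs(val_records, cfg.enum_mode, seed, cfg.representation)
    val_in, val_tgt = _encode_pairs(val_pairs, tok, vocab, max_len)

    for epoch in range(cfg.max_epochs):
        pairs = make_training_pairs(
            train_records, cfg.enum_mode, seed * 100_003 + epoch, cfg.representation
        )
        perm = rng.permutation(len(pairs))
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(pairs), cfg.batch_size):
            batch = [pairs[i] for i in perm[lo : lo + cfg.batch_size]]
            inp, tgt = _encode_pairs(batch, tok, vocab, max_len)
            total, _, _ = _batch_loss_graph(model, inp, tgt, rng)
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            epoch_loss += float(total.data)
            n_batches += 1
        history.train_loss.append(epoch_loss / max(1, n_batches))
        val_total, _, _ = _batch_loss_graph(model, val_in, val_tgt, None)
        history.val_loss.append(float(val_total.data))
        if check_early_stop(history.val_loss, cfg) == STOP:
            history.stop_reason = (
                "max_epochs" if history.epochs >= cfg.max_epochs else "early_stop"
            )
            break
    else:  # pragma: no cover - loop always breaks at max_epochs
        history.stop_reason = "max_epochs"
    if not history.stop_reason:
        history.stop_reason = "max_epochs"
    logger.info(
        "seed %d: stopped after %d epochs (%s), val loss %.4f",
        seed, history.epochs, history.stop_reason, history.val_loss[-1],
    )
    return SeedRun(seed, model, history)


def _encode_pairs(
    pairs: list[tuple[str, str]],
    tok: _Tokenizer,
    vocab: Vocabulary,
    max_len: int,
) -> tuple[OneHotBatch, OneHotBatch]:
    inputs = chemio.one_hot_encode([tok(a) for a, _ in pairs], vocab, max_len)
    targets = chemio.one_hot_encode([tok(b) for _, b in pairs], vocab, max_len)
    return inputs, targets


class AutoencoderExperiment:
    """Model-object surface: bind a corpus and a configuration, then
    :meth:`fit` to obtain :class:`FitResults`.

    Thin wrapper over :func:`train` for interactive use::

        exp = AutoencoderExperiment(records, ModelConfig(), TrainConfig())
        results = exp.fit()
        print(results.summary())
    """

    def __init__(
        self,
        records: list[MoleculeRecord],
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.records = records
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()

    def fit(self, evaluate_on_train: bool = True) -> FitResults:
        return train(
            self.model_config,
            self.train_config,
            self.records,
            evaluate_on=self.records if evaluate_on_train else None,
        )
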