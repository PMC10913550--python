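"""Training protocol: pairing modes, loss composition, the early-stopping
rule and the multi-seed loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molae import chemio
from molae.chemio import MoleculeRecord, Vocabulary, one_hot_encode, tokenize_smiles
from molae.fixtures import attach_enumerations, generate_loss_trace
from molae.metrics import aggregate_reports
from molae.model_core import ModelConfig
from molae.training import (
    CONTINUE,
    STOP,
    TrainConfig,
    check_early_stop,
    loss,
    make_training_pairs,
    train,
)

VOCAB = Vocabulary(("<pad>", "<sos>", "<eos>", "C", "N", "O"))


class TestTrainingPairs:
    @pytest.fixture()
    def records(self, corpus20):
        return attach_enumerations(list(corpus20[:10]), k=4, seed=2, selfies=True)

    def test_can2can_is_identity_pairing(self, records):
        pairs = make_training_pairs(records, "can2can", seed=0)
        assert len(pairs) == 10
        assert all(a == b for a, b in pairs)

    def test_enum2can_input_canonicalizes_to_target(self, records):
        for inp, tgt in make_training_pairs(records, "enum2can", seed=1):
            assert inp != tgt
            assert chemio.canonicalize(inp) == tgt

    def test_can2enum_target_canonicalizes_to_input(self, records):
        for inp, tgt in make_training_pairs(records, "can2enum", seed=1):
            assert chemio.canonicalize(tgt) == inp

    def test_selfies_pairing_uses_translated_enumerations(self, records):
        pairs = make_training_pairs(records, "enum2can", seed=1, representation="SELFIES")
        for inp, tgt in pairs:
            assert inp.startswith("[") and tgt.startswith("[")

    def test_missing_enumerations_rejected(self):
        with pytest.raises(ValueError, match="no SMILES enumerations"):
            make_training_pairs([MoleculeRecord("CCO")], "enum2can", seed=0)

    def test_resampling_differs_across_seeds(self, records):
        a = make_training_pairs(records, "enum2can", seed=1)
        b = make_training_pairs(records, "enum2can", seed=2)
        assert a != b
        assert a == make_training_pairs(records, "enum2can", seed=1)


class TestLoss:
    def _target(self, strings, max_len=5):
        return one_hot_encode([tokenize_smiles(s) for s in strings], VOCAB, max_len)

    def test_perfect_predictions_give_zero(self):
        tgt = self._target(["CCO", "CN"])
        assert loss(tgt.array, tgt) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_predictions_give_log_v(self):
        tgt = self._target(["CCO"])
        probs = np.full_like(tgt.array, 1.0 / len(VOCAB))
        assert loss(probs, tgt) == pytest.approx(np.log(len(VOCAB)))

    def test_variational_composition(self):
        """loss = CE + beta*KL: CE forced to 1.0, KL to 2.0, beta 0.3."""
        tgt = self._target(["CCO"])
        probs = np.where(tgt.array > 0, np.exp(-1.0), 0.1)
        mu = np.array([[2.0, 0.0]])  # KL = 0.5 * 4 = 2.0
        logvar = np.zeros((1, 2))
        assert loss(probs, tgt, mu, logvar, beta=0.3) == pytest.approx(1.6)

    def test_pad_positions_excluded(self):
        tgt = self._target(["CN"], max_len=8)
        probs = tgt.array.copy()
        probs[:, 3:, :] = 1.0 / len(VOCAB)  # garbage only on PAD positions
        assert loss(probs, tgt) == pytest.approx(0.0, abs=1e-12)


class TestEarlyStopping:
    CFG = TrainConfig()

    def test_never_stops_before_min_epochs(self):
        losses = [5.0] * 10  # flat from the start
        assert check_early_stop(losses, self.CFG) == CONTINUE
        assert check_early_stop([5.0] * 49, self.CFG) == CONTINUE

    def test_plateau_trace_stops_at_k_plus_patience(self):
        trace = generate_loss_trace("plateau_after_k", 60, seed=0, k=50)
        assert check_early_stop(trace[:54], self.CFG) == CONTINUE
        assert check_early_stop(trace[:55], self.CFG) == STOP

    def test_improving_trace_stops_only_at_max_epochs(self):
        trace = generate_loss_trace("improving", 500, seed=1)
        assert check_early_stop(trace[:499], self.CFG) == CONTINUE
        assert check_early_stop(trace, self.CFG) == STOP

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=520), st.integers(0, 5))
    def test_bounds_hold_for_arbitrary_traces(self, values, seed):
        decision = check_early_stop(values, self.CFG)
        if len(values) < self.CFG.min_epochs:
            assert decision == CONTINUE
        if len(values) >= self.CFG.max_epochs:
            assert decision == STOP


class TestTrainLoop:
    SMALL = ModelConfig("gru", 16, 16, 1)

    def test_three_seeds_aggregate_mean_min_max(self, corpus20):
        cfg = TrainConfig(seeds=(0, 1, 2), min_epochs=2, max_epochs=2, batch_size=8)
        results = train(self.SMALL, cfg, list(corpus20), evaluate_on=list(corpus20))
        assert len(results.runs) == 3
        agg = results.aggregate
        for key in ("mean_similarity", "full_reconstruction_rate"):
            entry = agg[key]
            assert len(entry["per_seed"]) == 3
            assert entry["min"] <= entry["mean"] <= entry["max"]
        assert "cell=gru" in results.summary()

    def test_identical_config_reproduces_losses(self, corpus20):
        cfg = TrainConfig(seeds=(1,), min_epochs=3, max_epochs=3, batch_size=8)
        a = train(self.SMALL, cfg, list(corpus20))
        b = train(self.SMALL, cfg, list(corpus20))
        assert a.runs[0].history.val_loss == b.runs[0].history.val_loss
        assert a.runs[0].history.train_loss == b.runs[0].history.train_loss

    def test_teacher_forced_memorization_of_two_molecules(self):
        """A model overfitted on a two-molecule corpus reproduces them
        under teacher forcing (and the training loss collapses)."""
        records = [MoleculeRecord("CCO"), MoleculeRecord("NCO")]
        cfg = TrainConfig(
            seeds=(0,), min_epochs=150, max_epochs=150, batch_size=2,
            holdout_validation=False,
        )
        results = train(ModelConfig("gru", 24, 24, 1), cfg, records)
        run = results.runs[0]
        assert run.history.train_loss[-1] < 0.05
        seqs = [tokenize_smiles(r.canonical_smiles) for r in records]
        batch = one_hot_encode(seqs, results.vocab, results.max_len)
        model = run.model
        _, strings = model.decode(model.encode(batch), results.max_len, teacher=batch)
        assert strings == ["CCO", "NCO"]

    def test_small_corpus_rejected(self):
        with pytest.raises(ValueError):
            train(self.SMALL, TrainConfig(), [MoleculeRecord("CCO")])

    def test_enum_mode_requires_enumerations(self, corpus20):
        cfg = TrainConfig(seeds=(0,), min_epochs=1, max_epochs=1, enum_mode="enum2can")
        with pytest.raises(ValueError):
            train(self.SMALL, cfg, [MoleculeRecord("CCO"), MoleculeRecord("CCN")])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(min_epochs=10, max_epochs=5)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(enum_mode="canXcan")
        with pytest.raises(ValueError):
            ModelConfig("rnnx")
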