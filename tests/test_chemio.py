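"""String handling: tokenizers, vocabulary, canonical forms, enumeration,
one-hot encoding and .smi round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molae import chemio
from molae.chemio import (
    EnumerationError,
    MoleculeRecord,
    SmilesParseError,
    TokenizationError,
    Vocabulary,
    build_vocabulary,
    canonicalize,
    decode_indices,
    enumerate_smiles,
    one_hot_encode,
    read_smi,
    tokenize_selfies,
    tokenize_smiles,
    write_smi,
)


class TestTokenizeSmiles:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("CCO", ["C", "C", "O"]),
            ("CCl", ["C", "Cl"]),
            ("BrCC", ["Br", "C", "C"]),
            ("C[nH]1ccc1", ["C", "[nH]", "1", "c", "c", "c", "1"]),
            ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
            ("CC(=O)O", ["C", "C", "(", "=", "O", ")", "O"]),
        ],
    )
    def test_token_splits(self, smiles, expected):
        assert list(tokenize_smiles(smiles).tokens) == expected

    def test_aromatic_ring_is_single_character_tokens(self):
        seq = tokenize_smiles("c1ccccc1")
        assert len(seq) == 8
        assert all(len(t) == 1 for t in seq.tokens)

    def test_concatenation_identity(self, corpus20):
        for rec in corpus20:
            seq = tokenize_smiles(rec.canonical_smiles)
            assert "".join(seq.tokens) == rec.canonical_smiles

    def test_unparseable_character_names_position(self):
        with pytest.raises(TokenizationError, match="position 2"):
            tokenize_smiles("CCXO")

    def test_empty_string_rejected(self):
        with pytest.raises(TokenizationError):
            tokenize_smiles("")


class TestTokenizeSelfies:
    @pytest.mark.parametrize(
        "selfies, expected",
        [
            ("[C][C][O]", ["[C]", "[C]", "[O]"]),
            ("[C][=O]", ["[C]", "[=O]"]),
            ("[C][Branch1][C][F]", ["[C]", "[Branch1]", "[C]", "[F]"]),
        ],
    )
    def test_bracket_split(self, selfies, expected):
        assert list(tokenize_selfies(selfies).tokens) == expected

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(TokenizationError):
            tokenize_selfies("[C][C")
        with pytest.raises(TokenizationError):
            tokenize_selfies("[C]x[C]")


class TestVocabulary:
    def test_specials_then_sorted_tokens(self):
        vocab = build_vocabulary([tokenize_smiles("CCO")])
        assert len(vocab) == 5  # PAD, SOS, EOS + {C, O}
        assert vocab.tokens[:3] == (chemio.PAD, chemio.SOS, chemio.EOS)
        assert vocab.tokens[3:] == ("C", "O")

    def test_indices_are_bijection(self):
        vocab = build_vocabulary([tokenize_smiles("CNO"), tokenize_smiles("OC")])
        assert sorted(vocab.index_of.values()) == list(range(len(vocab)))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])

    def test_mixed_representations_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            build_vocabulary([tokenize_smiles("CC"), tokenize_selfies("[C][C]")])

    def test_json_round_trip(self):
        vocab = build_vocabulary([tokenize_smiles("CC(=O)N")])
        assert Vocabulary.from_json(vocab.to_json()) == vocab


class TestCanonicalize:
    def test_same_molecule_same_string(self):
        assert canonicalize("OCC") == canonicalize("CCO")

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "CC(=O)Nc1ccccc1"])
    def test_idempotent(self, smiles):
        once = canonicalize(smiles)
        assert canonicalize(once) == once

    def test_unclosed_ring_rejected(self):
        with pytest.raises(SmilesParseError):
            canonicalize("C1CC")


class TestEnumerateSmiles:
    def test_variants_canonicalize_home_and_are_distinct(self):
        out = enumerate_smiles("CC(=O)NC1CC1", k=4, seed=3)
        assert len(out) == 4
        canonical = canonicalize("CC(=O)NC1CC1")
        assert all(canonicalize(v) == canonical for v in out)
        assert len({canonical, *out}) == 5

    def test_single_atom_rejected(self):
        with pytest.raises(EnumerationError):
            enumerate_smiles("C", k=1, seed=0)

    def test_deterministic_per_seed(self):
        a = enumerate_smiles("CCOC(=O)C", k=4, seed=9)
        b = enumerate_smiles("CCOC(=O)C", k=4, seed=9)
        assert a == b

    def test_unachievable_count_reports_achieved(self):
        with pytest.raises(EnumerationError, match="of 10"):
            enumerate_smiles("CO", k=10, seed=0)


class TestOneHot:
    def test_round_trip(self, small_vocab):
        seq = tokenize_smiles("CC(=O)N")
        batch = one_hot_encode([seq], small_vocab, max_len=10)
        assert decode_indices(batch.indices[0], small_vocab) == "CC(=O)N"

    def test_rows_are_one_hot_and_padding_convention(self, small_vocab):
        seq = tokenize_smiles("CCO")
        batch = one_hot_encode([seq], small_vocab, max_len=10)
        assert np.all(batch.array.sum(axis=2) == 1.0)
        assert batch.lengths[0] == 4  # 3 tokens + EOS
        assert batch.indices[0, 3] == small_vocab.eos_index
        assert np.all(batch.indices[0, 4:] == small_vocab.pad_index)

    def test_out_of_vocab_named(self, small_vocab):
        with pytest.raises(ValueError, match="'Cl'"):
            one_hot_encode([tokenize_smiles("CCl")], small_vocab, max_len=5)

    def test_overlength_rejected(self, small_vocab):
        with pytest.raises(ValueError, match="max_len"):
            one_hot_encode([tokenize_smiles("CCCCCC")], small_vocab, max_len=4)


class TestSmiFiles:
    def test_read_counts_and_skips(self, tmp_path):
        path = tmp_path / "mols.smi"
        path.write_text("CCO mol1\nnot_a_smiles\nc1ccccc1\n\nCC(=O)N\n")
        records, skipped = read_smi(path)
        assert len(records) == 3
        assert skipped == 1

    def test_write_read_round_trip(self, tmp_path, corpus20):
        path = tmp_path / "out.smi"
        write_smi(corpus20, path)
        records, skipped = read_smi(path)
        assert skipped == 0
        assert [r.canonical_smiles for r in records] == [
            r.canonical_smiles for r in corpus20
        ]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="CNOF=()1cno", min_size=1, max_size=20))
def test_tokenize_concatenation_identity_on_arbitrary_strings(s):
    """join(tokenize(s)) == s whenever tokenization succeeds at all."""
    try:
        seq = tokenize_smiles(s)
    except TokenizationError:
        return
    assert "".join(seq.tokens) == s
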