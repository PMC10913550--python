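"""Molecule string handling: tokenization, vocabularies, canonical forms,
enumeration, one-hot encoding and ``.smi`` file I/O.

Two string representations are supported throughout the package:

* **SMILES** — depth-first linear notation; many strings per molecule. The
  tokenizer is the community-standard regex scheme (bracket atoms as single
  tokens, two-letter elements ``Cl``/``Br``, ``%nn`` ring closures).
* **SELFIES** — bracket-delimited tokens with a robustness guarantee (every
  token sequence decodes to a molecule); see :mod:`molae.selfies_codec`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparsable SMILES; we log skips ourselves.
RDLogger.DisableLog("rdApp.error")

SMILES = "SMILES"
SELFIES = "SELFIES"

PAD = "<pad>"
SOS = "<sos>"
EOS = "<eos>"

_SMILES_TOKEN_RE = re.compile(
    r"\[[^\]]+\]"  # bracket atoms, single token
    r"|Br|Cl"      # two-letter organic-subset elements
    r"|%\d{2}"     # two-digit ring closures
    r"|[BCNOSPFI]" # organic subset
    r"|[bcnops]"   # aromatic atoms
    r"|[-=#$:/\\.+*]"
    r"|[()]"
    r"|\d"
)

_SELFIES_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")


class TokenizationError(ValueError):
    """Raised when a string cannot be split into known tokens."""


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized molecule string.

    Invariant: ``"".join(tokens) == source``. ``len(self)`` is the string
    length in tokens, the ``n`` used by the reconstruction metrics.
    """

    tokens: tuple[str, ...]
    representation: str
    source: str

    def __post_init__(self) -> None:
        if "".join(self.tokens) != self.source:
            raise ValueError("tokens do not concatenate to source")
        if len(self.tokens) < 1:
            raise ValueError("empty token sequence")

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_smiles(s: str) -> TokenSequence:
    """Split a SMILES string into tokens.

    Bracket atoms (``[nH]``), two-letter elements (``Cl``, ``Br``) and
    ``%nn`` ring closures are single tokens; everything else is one
    character per token.
    """
    if not s:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    while pos < len(s):
        m = _SMILES_TOKEN_RE.match(s, pos)
        if m is None:
            raise TokenizationError(
                f"unparseable character {s[pos]!r} at position {pos} in {s!r}"
            )
        tokens.append(m.group())
        pos = m.end()
    return TokenSequence(tuple(tokens), SMILES, s)


def tokenize_selfies(s: str) -> TokenSequence:
    """Split a SELFIES string into its bracket-delimited tokens."""
    if not s:
        raise TokenizationError("empty SELFIES string")
    tokens = _SELFIES_TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        raise TokenizationError(f"not a concatenation of [..] tokens: {s!r}")
    return TokenSequence(tuple(tokens), SELFIES, s)


def tokenize(s: str, representation: str) -> TokenSequence:
    if representation == SMILES:
        return tokenize_smiles(s)
    if representation == SELFIES:
        return tokenize_selfies(s)
    raise ValueError(f"unknown representation {representation!r}")


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token set shared by encoder input and decoder output.

    Specials come first (``PAD=0, SOS=1, EOS=2``) followed by the chemistry
    tokens in lexicographic order, which makes encodings bit-reproducible
    across runs.
    """

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.tokens[:3] != (PAD, SOS, EOS):
            raise ValueError("vocabulary must start with PAD, SOS, EOS")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def sos_index(self) -> int:
        return 1

    @property
    def eos_index(self) -> int:
        return 2

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens)})

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        return cls(tuple(json.loads(payload)["tokens"]))


def build_vocabulary(corpus: Sequence[TokenSequence]) -> Vocabulary:
    """Vocabulary over every distinct token in *corpus* plus the specials."""
    if not corpus:
        raise ValueError("empty corpus")
    reps = {seq.representation for seq in corpus}
    if len(reps) != 1:
        raise ValueError(f"mixed representations in corpus: {sorted(reps)}")
    chem = sorted({t for seq in corpus for t in seq.tokens})
    return Vocabulary((PAD, SOS, EOS) + tuple(chem))


class SmilesParseError(ValueError):
    """Raised when a SMILES string does not parse as a molecule."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """RDKit canonical SMILES; idempotent by construction."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


class EnumerationError(RuntimeError):
    """Raised when the requested number of distinct variants is unreachable."""


def enumerate_smiles(
    smiles: str, k: int, seed: int, max_retries_per_variant: int = 50
) -> list[str]:
    """``k`` distinct non-canonical SMILES of the same molecule.

    Variants are produced by random atom-order renumbering; duplicates of
    each other or of the canonical form are rejected and resampled, up to
    ``max_retries_per_variant`` draws each. Deterministic for a fixed seed.
    """
    mol = _mol_from_smiles(smiles)
    if mol.GetNumAtoms() < 2:
        raise EnumerationError(
            f"molecule {smiles!r} has fewer than 2 atoms; 0 of {k} variants achievable"
        )
    canonical = Chem.MolToSmiles(mol)
    rng = np.random.default_rng(seed)
    seen: set[str] = {canonical}
    out: list[str] = []
    budget = k * max_retries_per_variant
    while len(out) < k and budget > 0:
        budget -= 1
        order = rng.permutation(mol.GetNumAtoms()).tolist()
        variant = Chem.MolToSmiles(
            Chem.RenumberAtoms(mol, order), canonical=False
        )
        if variant in seen:
            continue
        seen.add(variant)
        out.append(variant)
    if len(out) < k:
        raise EnumerationError(
            f"could only produce {len(out)} of {k} distinct variants for {smiles!r}"
        )
    return out


@dataclass
class MoleculeRecord:
    """One molecule with its canonical SMILES and optional derived strings.

    ``enumerations`` are non-canonical SMILES of the same molecule;
    ``selfies_enumerations`` are their SELFIES translations (enumerated
    SELFIES are constructed from enumerated SMILES).
    """

    canonical_smiles: str
    selfies: str | None = None
    enumerations: list[str] = field(default_factory=list)
    selfies_enumerations: list[str] = field(default_factory=list)

    def canonical(self, representation: str) -> str:
        if representation == SMILES:
            return self.canonical_smiles
        if self.selfies is None:
            raise ValueError("record carries no SELFIES string")
        return self.selfies

    def enums(self, representation: str) -> list[str]:
        return self.enumerations if representation == SMILES else self.selfies_enumerations


@dataclass
class OneHotBatch:
    """One-hot encoded token sequences, ``[n_molecules, max_len, vocab]``.

    Each sequence is followed by EOS and then PAD rows out to ``max_len``;
    ``lengths`` counts tokens including the EOS.
    """

    array: np.ndarray
    lengths: np.ndarray
    vocab: Vocabulary

    @property
    def indices(self) -> np.ndarray:
        return self.array.argmax(axis=2)


def one_hot_encode(
    seqs: Sequence[TokenSequence], vocab: Vocabulary, max_len: int | None = None
) -> OneHotBatch:
    """Encode token sequences as a padded one-hot block (EOS appended)."""
    if not seqs:
        raise ValueError("no sequences to encode")
    lengths = np.array([len(s) + 1 for s in seqs], dtype=np.int64)  # + EOS
    if max_len is None:
        max_len = int(lengths.max())
    if lengths.max() > max_len:
        longest = max(seqs, key=len)
        raise ValueError(
            f"sequence {longest.source!r} needs {lengths.max()} positions "
            f"(incl. EOS) but max_len={max_len}"
        )
    arr = np.zeros((len(seqs), max_len, len(vocab)), dtype=np.float64)
    for i, seq in enumerate(seqs):
        for j, tok in enumerate(seq.tokens):
            idx = vocab.index_of.get(tok)
            if idx is None:
                raise ValueError(f"token {tok!r} not in vocabulary")
            arr[i, j, idx] = 1.0
        arr[i, len(seq), vocab.eos_index] = 1.0
        arr[i, len(seq) + 1 :, vocab.pad_index] = 1.0
    return OneHotBatch(arr, lengths, vocab)


def decode_indices(indices: Iterable[int], vocab: Vocabulary) -> str:
    """Indices back to a string, stopping at EOS and dropping specials."""
    out: list[str] = []
    for idx in indices:
        if idx == vocab.eos_index:
            break
        if idx in (vocab.pad_index, vocab.sos_index):
            continue
        out.append(vocab.tokens[idx])
    return "".join(out)


def read_smi(path: str | Path) -> tuple[list[MoleculeRecord], int]:
    """Read a ``.smi`` file (one SMILES per line, optional ID column).

    Returns the records plus the number of skipped lines (blank or failing
    canonicalization); skips are logged.
    """
    path = Path(path)
    records: list[MoleculeRecord] = []
    skipped = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) > 1:
            logger.debug("line %d: ignoring ID column %r", lineno, fields[1])
        try:
            records.append(MoleculeRecord(canonicalize(fields[0])))
        except SmilesParseError:
            skipped += 1
            logger.warning("line %d: skipping unparsable SMILES %r", lineno, fields[0])
    return records, skipped


def write_smi(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    Path(path).write_text(
        "".join(rec.canonical_smiles + "\n" for rec in records)
    )
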