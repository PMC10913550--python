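"""Synthetic molecule corpora and loss traces.

The molecule generator samples random SELFIES token sequences over a small
robust organic alphabet and decodes them; because any token combination
decodes to a valid molecule, the generator produces drug-like fragments
with bounded token length and a restricted element set (the character of
curated benchmark sets such as MOSES) without any download. The loss-trace
generator produces validation-loss curves with controlled improvement /
plateau structure for exercising the early-stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemio
from .chemio import MoleculeRecord, tokenize_selfies
from .selfies_codec import ROBUST_ALPHABET, selfies_to_smiles, smiles_to_selfies

#: Default fixture alphabet: a small organic subset so fixtures resemble
#: drug-like fragments. Index tokens are drawn from the same set.
DEFAULT_ALPHABET: tuple[str, ...] = (
    "[C]", "[=C]", "[N]", "[=N]", "[O]", "[=O]", "[F]", "[Branch1]", "[Ring1]",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus.

    ``ensure_enumerable`` rejects candidate molecules that do not admit that
    many distinct non-canonical SMILES; curated drug-like sets consist of
    asymmetric multi-atom molecules for which enumeration is always
    possible, and the augmentation protocol relies on it. Set 0 to disable.
    """

    n_molecules: int
    min_tokens: int = 3
    max_tokens: int = 15
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    seed: int = 0
    ensure_enumerable: int = 4

    def __post_init__(self) -> None:
        if not (1 <= self.min_tokens <= self.max_tokens):
            raise ValueError("need 1 <= min_tokens <= max_tokens")
        if not self.alphabet:
            raise ValueError("empty alphabet")
        for tok in self.alphabet:
            if not (tok.startswith("[") and tok.endswith("]")):
                raise ValueError(f"alphabet token {tok!r} is not bracket-delimited")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


class FixtureError(RuntimeError):
    """Raised when the requested number of distinct molecules is unreachable."""


def random_selfies(spec: FixtureSpec, rng: np.random.Generator) -> str:
    """One random token string over the spec's alphabet and length bounds."""
    length = int(rng.integers(spec.min_tokens, spec.max_tokens + 1))
    return "".join(rng.choice(spec.alphabet, size=length))


def generate_molecules(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Exactly ``spec.n_molecules`` records with distinct canonical SMILES.

    Deterministic per seed. Each record carries the canonical SMILES and its
    SELFIES encoding. Raises :class:`FixtureError` (reporting the achieved
    count) if the alphabet/length box cannot yield enough distinct molecules
    within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    budget = 200 * spec.n_molecules + 200
    while len(records) < spec.n_molecules and budget > 0:
        budget -= 1
        smiles = selfies_to_smiles(random_selfies(spec, rng))
        if not smiles or smiles in seen:
            continue
        if spec.ensure_enumerable:
            try:
                chemio.enumerate_smiles(smiles, spec.ensure_enumerable, spec.seed)
            except chemio.EnumerationError:
                continue
        seen.add(smiles)
        records.append(MoleculeRecord(smiles, selfies=smiles_to_selfies(smiles)))
    if len(records) < spec.n_molecules:
        raise FixtureError(
            f"could only generate {len(records)} of {spec.n_molecules} distinct "
            f"molecules for alphabet {spec.alphabet}"
        )
    return records


def attach_enumerations(
    records: list[MoleculeRecord], k: int = 4, seed: int = 0, selfies: bool = True
) -> list[MoleculeRecord]:
    """Fill each record with ``k`` non-canonical SMILES (and, optionally,
    their SELFIES translations), seeded per record."""
    for i, rec in enumerate(records):
        rec.enumerations = chemio.enumerate_smiles(rec.canonical_smiles, k, seed + i)
        if selfies:
            rec.selfies_enumerations = [smiles_to_selfies(s) for s in rec.enumerations]
    return records


def token_length_histogram(records: list[MoleculeRecord], representation: str) -> dict[int, int]:
    """Token-length counts of a corpus, for eyeballing corpus character."""
    counts: dict[int, int] = {}
    for rec in records:
        n = len(chemio.tokenize(rec.canonical(representation), representation))
        counts[n] = counts.get(n, 0) + 1
    return dict(sorted(counts.items()))


def token_frequencies(records: list[MoleculeRecord], representation: str) -> dict[str, float]:
    """Per-molecule-normalized token frequencies of a corpus."""
    counts: dict[str, float] = {}
    for rec in records:
        for tok in chemio.tokenize(rec.canonical(representation), representation).tokens:
            counts[tok] = counts.get(tok, 0.0) + 1.0
    return {t: c / len(records) for t, c in sorted(counts.items())}


def generate_loss_trace(
    pattern: str,
    length: int,
    seed: int = 0,
    k: int = 50,
    start: float = 3.0,
    min_delta: float = 0.01,
) -> list[float]:
    """Synthetic validation-loss trace.

    ``improving`` decreases by more than *min_delta* every step;
    ``plateau_after_k`` improves until step ``k`` (1-based) and then varies
    by less than *min_delta* around the step-``k`` value.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    value = start
    for step in range(length):
        if pattern == "improving" or (pattern == "plateau_after_k" and step < k):
            value -= min_delta * (1.5 + rng.random())
            trace.append(value)
        elif pattern == "plateau_after_k":
            trace.append(trace[k - 1] + (rng.random() - 0.5) * min_delta * 0.9)
        else:
            raise ValueError(f"unknown pattern {pattern!r}")
    return trace
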