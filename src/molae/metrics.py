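"""Reconstruction metrics: Mean Similarity, Levenshtein similarity, and the
Full Reconstruction rate.

All three operate on *token* sequences, not characters, so a two-letter
element such as ``Cl`` counts as one unit. ``n`` in the normalized metrics
is always the input (ground-truth) token count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemio import TokenSequence


def _check_pair(a: TokenSequence, b: TokenSequence) -> None:
    if a.representation != b.representation:
        raise ValueError(
            f"mixed representations: {a.representation} vs {b.representation}"
        )


def mean_similarity(inp: TokenSequence, recon: TokenSequence | None) -> float:
    """Fraction of positions 1..n whose tokens match, n = input length.

    Positions past the end of the reconstruction score 0; reconstruction
    tokens past position n are ignored.
    """
    if recon is not None:
        _check_pair(inp, recon)
    n = len(inp)
    if n == 0:
        raise ValueError("empty input sequence")
    if recon is None:
        return 0.0
    hits = sum(
        1 for i in range(min(n, len(recon))) if inp.tokens[i] == recon.tokens[i]
    )
    return hits / n


def levenshtein_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Token-level edit distance (substitutions, insertions, deletions)."""
    a = list(a)
    b = list(b)
    if len(a) < len(b):  # keep the DP row short
        a, b = b, a
    prev = np.arange(len(b) + 1)
    for i, tok_a in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, tok_b in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,            # deletion
                cur[j - 1] + 1,         # insertion
                prev[j - 1] + (tok_a != tok_b),  # substitution
            )
        prev = cur
    return int(prev[len(b)])


def levenshtein_similarity(inp: TokenSequence, recon: TokenSequence | None) -> float:
    """``1 - LD/n`` with n the input token count, clamped below at 0."""
    n = len(inp)
    if n == 0:
        raise ValueError("empty input sequence")
    if recon is None:
        return 0.0
    _check_pair(inp, recon)
    ld = levenshtein_distance(inp.tokens, recon.tokens)
    return max(0.0, 1.0 - ld / n)


def exact_match(inp: TokenSequence, recon: TokenSequence | None) -> bool:
    return recon is not None and inp.tokens == recon.tokens


def full_reconstruction_rate(
    pairs: Sequence[tuple[TokenSequence, TokenSequence | None]]
) -> float:
    """Percentage of pairs reconstructed without a single token mismatch."""
    if not pairs:
        raise ValueError("no pairs to score")
    return 100.0 * sum(exact_match(i, r) for i, r in pairs) / len(pairs)


@dataclass
class ReconstructionReport:
    """Per-molecule and aggregate reconstruction metrics."""

    per_molecule: pd.DataFrame  # input, reconstruction, mean_similarity,
    #                             levenshtein_similarity, exact_match
    skipped: int = 0

    @property
    def mean_similarity(self) -> float:
        return float(self.per_molecule["mean_similarity"].mean())

    @property
    def levenshtein_similarity(self) -> float:
        return float(self.per_molecule["levenshtein_similarity"].mean())

    @property
    def full_reconstruction_rate(self) -> float:
        return 100.0 * float(self.per_molecule["exact_match"].mean())

    def to_dict(self) -> dict:
        return {
            "mean_similarity": self.mean_similarity,
            "levenshtein_similarity": self.levenshtein_similarity,
            "full_reconstruction_rate": self.full_reconstruction_rate,
            "n_molecules": int(len(self.per_molecule)),
            "skipped": self.skipped,
        }


def score_pairs(
    pairs: Sequence[tuple[TokenSequence, TokenSequence | None]], skipped: int = 0
) -> ReconstructionReport:
    """Score (input, reconstruction) token-sequence pairs.

    A ``None`` reconstruction (e.g. the decoder emitted EOS immediately)
    scores 0 on both similarities.
    """
    if not pairs:
        raise ValueError("no pairs to score")
    rows = []
    for inp, rec in pairs:
        rows.append(
            {
                "input": inp.source,
                "reconstruction": "" if rec is None else rec.source,
                "mean_similarity": mean_similarity(inp, rec),
                "levenshtein_similarity": levenshtein_similarity(inp, rec),
                "exact_match": exact_match(inp, rec),
            }
        )
    return ReconstructionReport(pd.DataFrame(rows), skipped=skipped)


@dataclass
class SeedAggregate:
    """Mean / min / max of a metric across per-seed runs, the figures'
    error-bar convention (bar = mean, whiskers = lowest and highest seed)."""

    values: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))

    def to_dict(self) -> dict:
        return {
            "per_seed": [float(v) for v in self.values],
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
        }


def aggregate_reports(reports: Sequence[ReconstructionReport]) -> dict[str, dict]:
    """Across-seed aggregation of the three headline metrics."""
    if not reports:
        raise ValueError("no reports to aggregate")
    return {
        "mean_similarity": SeedAggregate([r.mean_similarity for r in reports]).to_dict(),
        "levenshtein_similarity": SeedAggregate(
            [r.levenshtein_similarity for r in reports]
        ).to_dict(),
        "full_reconstruction_rate": SeedAggregate(
            [r.full_reconstruction_rate for r in reports]
        ).to_dict(),
    }


def evaluate_model(model, records, representation: str) -> ReconstructionReport:
    """Free-running evaluation of a trained autoencoder.

    Each record's canonical string (in *representation*) is encoded and
    greedily decoded without teacher forcing; molecules containing tokens
    outside the model vocabulary are skipped with a warning and counted in
    ``report.skipped``.
    """
    import logging

    from . import chemio

    logger = logging.getLogger(__name__)
    seqs: list[TokenSequence] = []
    skipped = 0
    for rec in records:
        seq = chemio.tokenize(rec.canonical(representation), representation)
        unknown = [t for t in seq.tokens if t not in model.vocab.index_of]
        if unknown:
            skipped += 1
            logger.warning(
                "skipping %r: tokens %s not in model vocabulary", seq.source, unknown
            )
            continue
        seqs.append(seq)
    if not seqs:
        raise ValueError("no decodable molecules in the evaluation set")
    max_in = max(len(s) for s in seqs) + 1
    batch = chemio.one_hot_encode(seqs, model.vocab, max_in)
    latents = model.encode(batch)
    # decode headroom past the longest input so overlong reconstructions
    # are visible to the metrics rather than silently truncated
    _, strings = model.greedy_decode(latents, max_len=max_in + max(4, max_in // 2))
    pairs: list[tuple[TokenSequence, TokenSequence | None]] = []
    for inp, recon in zip(seqs, strings):
        pairs.append((inp, chemio.tokenize(recon, representation) if recon else None))
    return score_pairs(pairs, skipped=skipped)
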