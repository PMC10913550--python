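"""Latent-space diagnostics.

Two families of checks on a trained encoder:

* **Utilization typing** — min-max scale the latent matrix per dimension,
  look at per-dimension variances, and classify the space as posterior
  collapse (nearly all dimensions dead), high utilization (essentially all
  alive) or selective utilization (a blend of live and dead dimensions,
  i.e. more capacity than the reconstruction needs). The reference
  typology is visual; the thresholds here make it computable and are
  recorded in every report.

* **Chemical-similarity geometry** — embed a large random background plus
  a few test molecules with their enumerations (same molecule, different
  strings), project everything with one jointly-fitted PCA, and compare
  within-group Euclidean distances against the background pairwise-distance
  distribution. An encoder that reflects chemistry maps enumerations of a
  molecule close together relative to random pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import chemio
from .chemio import MoleculeRecord
from .model_core import LatentMatrix, MoleculeAutoencoder
from .selfies_codec import SelfiesError, smiles_to_selfies

logger = logging.getLogger(__name__)

POSTERIOR_COLLAPSE = "posterior_collapse"
HIGH_UTILIZATION = "high_utilization"
SELECTIVE = "selective"


def minmax_scale(latents: LatentMatrix | np.ndarray) -> np.ndarray:
    """Per-dimension (column) min-max scaling to [0, 1]; constant columns
    map to all-zeros."""
    values = latents.values if isinstance(latents, LatentMatrix) else np.asarray(latents)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    return (values - lo) / safe


def global_minmax_scale(values: np.ndarray) -> np.ndarray:
    """Whole-matrix min-max scaling to [0, 1] (one scale per latent
    matrix). Unlike per-dimension scaling this preserves the relative
    spread of the dimensions, so a collapsed space — every dimension near
    its own constant, the heatmap's striping pattern — keeps near-zero
    per-dimension variance instead of having its jitter inflated to full
    range. A constant matrix maps to all-zeros."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


@dataclass
class UtilizationReport:
    """Min-max-scaled latents, per-dimension variances and the typology
    label, together with the thresholds that produced it."""

    scaled: np.ndarray
    dim_variances: np.ndarray
    fraction_low: float
    label: str
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "fraction_low": self.fraction_low,
            "dim_variances": self.dim_variances.tolist(),
            "thresholds": self.thresholds,
        }


def classify_utilization(
    latents: LatentMatrix | np.ndarray,
    tau_low: float = 0.01,
    collapse_frac: float = 0.9,
    selective_frac: float = 0.05,
) -> UtilizationReport:
    """Type a latent space from its scaled per-dimension variances.

    The matrix is min-max scaled as a whole (one scale per model, the
    convention that keeps collapse visible as near-constant dimensions);
    a dimension is "low" when its scaled variance falls below ``tau_low``.
    With ``f`` the fraction of low dimensions: ``f >= collapse_frac`` is
    posterior collapse, ``selective_frac <= f < collapse_frac`` is
    selective utilization, and anything below is high utilization.
    """
    values = latents.values if isinstance(latents, LatentMatrix) else np.asarray(latents)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    scaled = global_minmax_scale(values)
    variances = scaled.var(axis=0)
    fraction_low = float((variances < tau_low).mean())
    if fraction_low >= collapse_frac:
        label = POSTERIOR_COLLAPSE
    elif fraction_low >= selective_frac:
        label = SELECTIVE
    else:
        label = HIGH_UTILIZATION
    return UtilizationReport(
        scaled,
        variances,
        fraction_low,
        label,
        thresholds={
            "tau_low": tau_low,
            "collapse_frac": collapse_frac,
            "selective_frac": selective_frac,
        },
    )


@dataclass
class ColocalizationReport:
    """Joint PCA of background + enumeration-group embeddings."""

    background_coords: np.ndarray          # (n_background, 2)
    group_coords: list[np.ndarray]         # per test molecule, (k+1, 2)
    explained_variance_percent: np.ndarray # over all components, sums to 100
    group_mean_distances: list[float]      # mean within-group pairwise dist
    background_distance_sample: np.ndarray

    def to_dict(self) -> dict:
        return {
            "explained_variance_percent": self.explained_variance_percent.tolist(),
            "group_mean_distances": self.group_mean_distances,
            "background_distance_median": float(
                np.median(self.background_distance_sample)
            ),
        }


def _embed_strings(
    model: MoleculeAutoencoder, strings: list[str], representation: str
) -> np.ndarray:
    seqs = [chemio.tokenize(s, representation) for s in strings]
    max_len = max(len(s) for s in seqs) + 1
    return model.encode(chemio.one_hot_encode(seqs, model.vocab, max_len)).values


def _pairwise_distances(x: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle Euclidean distances."""
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(len(x), k=1)
    return d[iu]


def enumeration_colocalization(
    model: MoleculeAutoencoder,
    records: list[MoleculeRecord],
    representation: str = chemio.SMILES,
    n_background: int = 10_000,
    n_test: int = 3,
    k_enum: int = 4,
    seed: int = 0,
) -> ColocalizationReport:
    """Do enumerations of one molecule co-locate in latent space?

    ``n_test`` molecules are drawn from *records* and enumerated ``k_enum``
    times (for SELFIES models the enumerated SMILES are translated), giving
    ``k_enum + 1`` strings per molecule. These, plus ``n_background``
    random molecules, are embedded and projected with one PCA fitted on all
    embeddings jointly.
    """
    rng = np.random.default_rng(seed)
    if len(records) < n_background:
        logger.warning(
            "background pool has %d molecules < requested %d; using all",
            len(records), n_background,
        )
        background = list(records)
    else:
        idx = rng.choice(len(records), size=n_background, replace=False)
        background = [records[i] for i in idx]

    def in_vocab(s: str) -> bool:
        return all(
            t in model.vocab.index_of
            for t in chemio.tokenize(s, representation).tokens
        )

    candidates = rng.permutation(len(records))
    groups: list[list[str]] = []
    for i in candidates:
        if len(groups) == n_test:
            break
        rec = records[i]
        # oversample where possible, then keep variants the model
        # vocabulary covers
        enums = None
        for attempt_k in (3 * k_enum, k_enum):
            try:
                enums = chemio.enumerate_smiles(
                    rec.canonical_smiles, attempt_k, seed=seed + int(i)
                )
                break
            except chemio.EnumerationError as exc:
                last_error = exc
        if enums is None:
            logger.warning("resampling test molecule: %s", last_error)
            continue
        if representation == chemio.SELFIES:
            try:
                enums = [smiles_to_selfies(s) for s in enums]
            except SelfiesError as exc:
                logger.warning("resampling test molecule: %s", exc)
                continue
        usable = [s for s in enums if in_vocab(s)][:k_enum]
        if len(usable) < k_enum:
            logger.warning(
                "resampling test molecule %r: only %d of %d enumerations "
                "covered by the model vocabulary",
                rec.canonical_smiles, len(usable), k_enum,
            )
            continue
        groups.append([rec.canonical(representation)] + usable)
    if len(groups) < n_test:
        raise ValueError(f"only {len(groups)} of {n_test} test molecules enumerable")

    bg_emb = _embed_strings(
        model, [r.canonical(representation) for r in background], representation
    )
    group_embs = [_embed_strings(model, g, representation) for g in groups]

    stacked = np.vstack([bg_emb] + group_embs)
    pca = PCA(n_components=min(stacked.shape))
    coords = pca.fit_transform(stacked)
    percents = 100.0 * pca.explained_variance_ratio_

    group_coords = []
    offset = len(bg_emb)
    means = []
    for emb in group_embs:
        group_coords.append(coords[offset : offset + len(emb), :2])
        means.append(float(_pairwise_distances(emb).mean()))
        offset += len(emb)
    return ColocalizationReport(
        coords[: len(bg_emb), :2],
        group_coords,
        percents,
        means,
        _pairwise_distances(bg_emb if len(bg_emb) <= 1000 else bg_emb[:1000]),
    )


@dataclass
class DistanceSeparation:
    """Background pairwise distances vs within-group means."""

    background_distances: np.ndarray
    group_means: list[float]


def distance_separation(
    model: MoleculeAutoencoder,
    records: list[MoleculeRecord],
    test_groups: list[list[str]],
    representation: str = chemio.SMILES,
    n_random: int = 1000,
    seed: int = 0,
    max_pairs: int = 500_000,
) -> DistanceSeparation:
    """Pairwise Euclidean distances of ``n_random`` random embeddings (the
    histogram background) plus each group's mean within-group distance."""
    rng = np.random.default_rng(seed)
    n = min(n_random, len(records))
    if n < len(records):
        idx = rng.choice(len(records), size=n, replace=False)
        sample = [records[i] for i in idx]
    else:
        sample = list(records)
    emb = _embed_strings(
        model, [r.canonical(representation) for r in sample], representation
    )
    distances = _pairwise_distances(emb)
    if len(distances) > max_pairs:
        distances = rng.choice(distances, size=max_pairs, replace=False)
    group_means = []
    for group in test_groups:
        gemb = _embed_strings(model, group, representation)
        group_means.append(float(_pairwise_distances(gemb).mean()))
    return DistanceSeparation(distances, group_means)
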