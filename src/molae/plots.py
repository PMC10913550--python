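"""Figure helpers: utilization heatmaps, PCA scatter, distance histograms,
and corpus character plots. All write straight to an image file."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .latent_diagnostics import ColocalizationReport, UtilizationReport


def utilization_heatmap(report: UtilizationReport, path: str | Path) -> None:
    """Molecule-by-dimension heatmap of min-max-scaled latents, rows in
    input order."""
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(report.scaled, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("latent dimension")
    ax.set_ylabel("molecule")
    ax.set_title(f"latent utilization: {report.label}")
    fig.colorbar(im, ax=ax, label="scaled activation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scatter(report: ColocalizationReport, path: str | Path) -> None:
    """Background cloud in gray, enumeration groups as colored markers."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        report.background_coords[:, 0], report.background_coords[:, 1],
        s=4, c="lightgray", label="random molecules",
    )
    for i, coords in enumerate(report.group_coords):
        ax.scatter(coords[0, 0], coords[0, 1], marker="o", s=60, label=f"molecule {i+1}")
        ax.scatter(coords[1:, 0], coords[1:, 1], marker="x", s=40)
    ev = report.explained_variance_percent
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def distance_histogram(
    background: np.ndarray, group_means: list[float], path: str | Path
) -> None:
    """Histogram of background pairwise distances with vertical lines at
    each group's mean within-group distance."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(background, bins=50, color="steelblue", alpha=0.8)
    for i, mean in enumerate(group_means):
        ax.axvline(mean, color=f"C{i+1}", linestyle="--", label=f"molecule {i+1}")
    ax.set_xlabel("Euclidean distance")
    ax.set_ylabel("pairs")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def corpus_character(
    length_hist: dict[int, int], token_freq: dict[str, float], path: str | Path
) -> None:
    """Token-length distribution and per-molecule token frequencies."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.bar(list(length_hist.keys()), list(length_hist.values()), color="teal")
    ax1.set_xlabel("token length")
    ax1.set_ylabel("molecules")
    ax2.bar(range(len(token_freq)), list(token_freq.values()), color="orange")
    ax2.set_xticks(range(len(token_freq)))
    ax2.set_xticklabels(list(token_freq.keys()), rotation=90, fontsize=6)
    ax2.set_ylabel("mean count per molecule")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
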