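"""Figure helpers: fingerprint-matrix heatmaps and permutation-null plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fingerprint import FingerprintMatrix, NullDistribution

__all__ = ["plot_fingerprint_matrix", "plot_null_histogram"]


def plot_fingerprint_matrix(matrix: FingerprintMatrix, path: str | Path) -> None:
    """Heatmap with a cross marking each row's maximum (the identification)."""
    M = matrix.values
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(M, cmap="viridis", aspect="equal")
    for i in range(M.shape[0]):
        ax.plot(int(np.argmax(M[i])), i, "rx", ms=6, mew=1.5)
    ax.set_xlabel("subject (experiment 2)")
    ax.set_ylabel("subject (experiment 1)")
    ax.set_title(f"{matrix.scheme} ({matrix.feature_set})")
    fig.colorbar(im, ax=ax, label="mean correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_null_histogram(null: NullDistribution, path: str | Path, label: str = "") -> None:
    """Null histogram with an arrow at the observed statistic."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(null.samples, bins=60, color="0.7")
    y = ax.get_ylim()[1]
    ax.annotate(
        f"observed = {null.observed:.3f}\np = {null.p_value:.2g}",
        xy=(null.observed, 0.0),
        xytext=(null.observed, 0.55 * y),
        arrowprops=dict(arrowstyle="->", color="crimson"),
        ha="center",
        fontsize=8,
    )
    ax.set_xlabel("statistic under permutation")
    ax.set_ylabel("count")
    if label:
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
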