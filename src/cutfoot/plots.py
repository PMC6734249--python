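"""Convenience image exports: cut-matrix heatmap and footprint profile."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cutmatrix import CutMatrix, aggregate_profile

__all__ = ["plot_cut_matrix", "plot_footprint_profile"]


def plot_cut_matrix(
    m: CutMatrix, path: Union[str, Path], max_sites: int = 2000
) -> None:
    """Heatmap of the combined cut matrix, rows ordered by read total."""
    combined = m.combined()
    order = np.argsort(combined.sum(axis=1))[::-1][:max_sites]
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(
        np.log1p(combined[order]),
        aspect="auto",
        interpolation="nearest",
        cmap="Blues",
    )
    ax.set_xlabel("oriented position")
    ax.set_ylabel("motif site (by read total)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_footprint_profile(
    m: CutMatrix,
    path: Union[str, Path],
    lam: Optional[np.ndarray] = None,
) -> None:
    """Strand-specific aggregate cut frequencies, optionally with the fitted
    per-position cut probability overlaid on a twin axis."""
    prof = aggregate_profile(m)
    x = np.arange(m.width)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(x, prof["forward"], label="forward cuts", lw=0.9)
    ax.plot(x, prof["reverse"], label="reverse cuts", lw=0.9)
    ax.set_xlabel("oriented position")
    ax.set_ylabel("cut count")
    if lam is not None:
        ax2 = ax.twinx()
        w = m.width
        oriented = lam[:w] + lam[w:] if lam.size == 2 * w else lam
        ax2.plot(x, oriented, color="k", ls="--", lw=0.8, label="model lambda")
        ax2.set_ylabel("cut probability")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
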