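"""Minimal figure exports (NMDS scatter, rarefaction curves)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .community import OrdinationResult

__all__ = ["plot_nmds", "plot_rarefaction"]


def plot_nmds(result: OrdinationResult, labels: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = sorted(set(labels[s] for s in result.ids))
    for g in groups:
        idx = [i for i, s in enumerate(result.ids) if labels[s] == g]
        ax.scatter(
            result.coordinates[idx, 0], result.coordinates[idx, 1], s=12, label=g
        )
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"NMDS (stress-1 = {result.stress:.3f})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_rarefaction(curves: pd.DataFrame, path: str | Path) -> Path:
    """``curves`` has columns sample_id, depth, median_shannon."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    for sid, sub in curves.groupby("sample_id"):
        ax.plot(sub["depth"], sub["median_shannon"], lw=0.5, alpha=0.5)
    ax.set_xlabel("rarefaction depth (reads)")
    ax.set_ylabel("median Shannon index")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
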