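"""Figures: positional variance diagrams and stage-proportion bars."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ordering import PositionalVariance


def _draw_pvd(ax, pvd: PositionalVariance, title: str) -> None:
    n = pvd.matrix.shape[0]
    # grayscale, darker = higher posterior confidence
    ax.imshow(pvd.matrix, cmap="Greys", vmin=0.0, vmax=1.0, aspect="equal")
    ax.set_yticks(range(n))
    ax.set_yticklabels(pvd.row_labels, fontsize=7)
    ax.set_xticks(range(n))
    ax.set_xticklabels(range(1, n + 1), fontsize=7)
    ax.set_xlabel("sequence position")
    ax.set_title(title, fontsize=9)


def plot_pvd(
    pvds: PositionalVariance | Sequence[PositionalVariance],
    titles: Sequence[str] | None = None,
    path: str | Path | None = None,
):
    """Render one or more PVDs side by side (inferred order on the y-axis,
    top to bottom; darker squares = more certain position)."""
    if isinstance(pvds, PositionalVariance):
        pvds = [pvds]
    titles = titles or [f"PVD {i + 1}" for i in range(len(pvds))]
    n = pvds[0].matrix.shape[0]
    fig, axes = plt.subplots(
        1, len(pvds), figsize=(0.45 * n * len(pvds) + 2.5, 0.45 * n + 1.5),
        squeeze=False,
    )
    for ax, pvd, title in zip(axes[0], pvds, titles):
        _draw_pvd(ax, pvd, title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_stage_proportions(
    proportions: pd.DataFrame, path: str | Path | None = None
):
    """Grouped bar chart of the per-group stage distribution."""
    n_stages = proportions.shape[1]
    x = np.arange(n_stages)
    width = 0.8 / len(proportions)
    fig, ax = plt.subplots(figsize=(0.6 * n_stages + 2, 3.2))
    for i, (group, row) in enumerate(proportions.iterrows()):
        ax.bar(x + i * width, row.to_numpy(), width, label=str(group))
    ax.set_xticks(x + width * (len(proportions) - 1) / 2)
    ax.set_xticklabels(range(n_stages))
    ax.set_xlabel("biomarker stage")
    ax.set_ylabel("proportion of subjects")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
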