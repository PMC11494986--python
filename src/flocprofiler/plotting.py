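"""Minimal figure exports: a pathway z-score heatmap and a quality-tier bar
chart.  Requires matplotlib (``pip install flocprofiler[plot]``)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .quality import QualityAssessment, tier_counts


def pathway_heatmap(zscores: pd.DataFrame, path: str | Path) -> None:
    """Save a pathway-by-sample z-score heatmap to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(0.6 * zscores.shape[1] + 3, 0.35 * zscores.shape[0] + 2)
    )
    im = ax.imshow(zscores.to_numpy(), cmap="RdBu_r", vmin=-2.5, vmax=2.5, aspect="auto")
    ax.set_xticks(range(zscores.shape[1]), zscores.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(zscores.shape[0]), zscores.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="gene count (row z-score)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tier_barplot(assessments: Sequence[QualityAssessment], path: str | Path) -> None:
    """Save a bar chart of high/medium/fail tier counts to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = tier_counts(assessments)
    tiers = ["high", "medium", "fail"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(tiers, [counts[t] for t in tiers], color=["#2c7fb8", "#7fcdbb", "#bdbdbd"])
    ax.bar(["MIMAG"], [counts["mimag_high"]], color="#253494")
    ax.set_ylabel("genomes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
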