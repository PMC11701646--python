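"""Dot-plot rendering of enrichment results.

One dot per kept term: enrichment signal on the x-axis, a discrete
10-step color ramp over -log10(FDR), dot area linear in the observed
protein count, and similarity groups annotated along the right edge.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm

from .enrich import PlotRecord

_FDR_FLOOR = 1e-10


def render_dotplot(
    records: Sequence[PlotRecord],
    path: str | Path,
    title: str = "Enrichment",
) -> None:
    """Render plot records to an SVG (or any matplotlib-supported) file."""
    path = Path(path)
    if not records:
        fig, ax = plt.subplots(figsize=(6, 2))
        ax.text(0.5, 0.5, "no enriched terms", ha="center", va="center")
        ax.axis("off")
        fig.savefig(path)
        plt.close(fig)
        return

    records = sorted(records, key=lambda r: r.y_rank)
    x = np.array([r.x_signal for r in records])
    neglog_fdr = np.array([-np.log10(max(r.fdr, _FDR_FLOOR)) for r in records])
    counts = np.array([r.size_observed for r in records])
    y = np.arange(len(records))[::-1]  # best term on top

    # 10-step discrete ramp over -log10(FDR); dot area linear in count
    bounds = np.linspace(0.0, max(neglog_fdr.max(), 1.0), 11)
    norm = BoundaryNorm(bounds, ncolors=256)
    sizes = 30.0 + 170.0 * counts / max(counts.max(), 1)

    height = max(2.0, 0.35 * len(records) + 1.2)
    fig, ax = plt.subplots(figsize=(7, height))
    scatter = ax.scatter(x, y, s=sizes, c=neglog_fdr, cmap="viridis", norm=norm,
                         edgecolor="black", linewidth=0.4, zorder=3)
    ax.set_yticks(y)
    ax.set_yticklabels([r.description for r in records], fontsize=8)
    ax.set_xlabel("enrichment signal")
    ax.set_title(title)
    ax.grid(axis="x", linestyle=":", linewidth=0.5, zorder=0)
    fig.colorbar(scatter, ax=ax, label="-log10(FDR)")

    # group spans annotated on the right
    xmax = ax.get_xlim()[1]
    current = None
    span_start = None
    for yy, rec in zip(y, records):
        if rec.group != current:
            if current is not None and span_start is not None:
                ax.annotate(current, xy=(xmax, (span_start + prev_y) / 2),
                            xycoords="data", fontsize=7, color="gray")
            current, span_start = rec.group, yy
        prev_y = yy
    if current is not None and span_start is not None:
        ax.annotate(current, xy=(xmax, (span_start + prev_y) / 2),
                    xycoords="data", fontsize=7, color="gray")

    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
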