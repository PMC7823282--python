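"""Concordance heatmap grids: one method-by-method panel per grid cell.

Undefined Jaccard values (no predictions by either method of a pair) are
rendered white, distinguishing "no evidence" from "zero agreement".
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .concordance import ConcordanceMatrix  # noqa: E402
from .filtering import FilterRegion  # noqa: E402


def plot_concordance_grid(grid: Mapping[FilterRegion, ConcordanceMatrix],
                          path: str | Path) -> None:
    """Render the full (cutoff x window) grid of pairwise-Jaccard heatmaps."""
    cutoffs = sorted({r.expression_cutoff for r in grid})
    windows = sorted({(r.fc_lower, r.fc_upper) for r in grid})
    fig, axes = plt.subplots(
        len(windows), len(cutoffs),
        figsize=(2.2 * len(cutoffs), 2.2 * len(windows)),
        squeeze=False,
    )
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("white")
    im = None
    for i, window in enumerate(windows):
        for j, cutoff in enumerate(cutoffs):
            ax = axes[i][j]
            region = FilterRegion(cutoff, *window)
            cm = grid[region]
            data = np.ma.masked_invalid(cm.values.to_numpy())
            im = ax.imshow(data, vmin=0, vmax=1, cmap=cmap)
            ax.set_xticks(range(len(cm.method_ids)))
            ax.set_yticks(range(len(cm.method_ids)))
            if i == len(windows) - 1:
                ax.set_xticklabels(cm.method_ids, rotation=90, fontsize=6)
            else:
                ax.set_xticklabels([])
            if j == 0:
                ax.set_yticklabels(cm.method_ids, fontsize=6)
            else:
                ax.set_yticklabels([])
            if i == 0:
                ax.set_title(f"cutoff {cutoff:g}", fontsize=8)
        upper = ("inf" if math.isinf(windows[i][1])
                 else f"{windows[i][1]:g}")
        axes[i][0].set_ylabel(f"FC [{windows[i][0]:g},{upper})", fontsize=8)
    if im is not None:
        fig.colorbar(im, ax=axes, shrink=0.6, label="Jaccard index")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
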