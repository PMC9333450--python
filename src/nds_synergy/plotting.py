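"""Minimal score visualisation: log2 TSS/ESS histograms by combination size."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def score_histograms(scores: pd.DataFrame, out: str | Path | None = None):
    """Histogram log2 TSS and log2 ESS across subsets, split by subset size.

    Mirrors the standard way screen-wide synergy results are summarized:
    a log2 ESS of 0 means no emergent synergy, each unit below 0 is one
    two-fold dilution step of improvement.
    """
    sizes = sorted(s for s in scores["size"].unique() if s >= 2)
    fig, axes = plt.subplots(
        len(sizes), 2, figsize=(8, 2.0 * max(len(sizes), 1)), squeeze=False, sharex=True
    )
    for row, size in enumerate(sizes):
        sub = scores[scores["size"] == size]
        for col, metric in enumerate(("log2_tss", "log2_ess")):
            ax = axes[row][col]
            vals = sub[metric].dropna()
            if len(vals):
                lo, hi = np.floor(vals.min()) - 0.5, np.ceil(vals.max()) + 0.5
                ax.hist(vals, bins=np.arange(lo, hi + 1.0, 1.0), edgecolor="black")
            ax.set_ylabel(f"|set|={size}")
            if row == 0:
                ax.set_title(metric.replace("log2_", "log2 ").upper())
            if row == len(sizes) - 1:
                ax.set_xlabel("log2 score")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
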