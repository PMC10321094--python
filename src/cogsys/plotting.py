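"""Basic diagnostic plots: Manhattan and NES bar chart."""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan(assoc_table: pd.DataFrame, ax=None, sig_line: float = 5e-8):
    """Manhattan plot of -log10(p) by genome position, colored per chromosome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(assoc_table.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        y = -np.log10(grp["p"].to_numpy())
        ax.scatter(x, y, s=4, color=f"C{i % 2}", rasterized=True)
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max() + 1
    ax.axhline(-np.log10(sig_line), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax


def nes_bars(enrichment_table: pd.DataFrame, ax=None, top: int = 20):
    """Horizontal bars of the top pathways by normalized enrichment score."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
    t = enrichment_table.head(top).iloc[::-1]
    colors = np.where(t["q"] <= 0.05, "C3", "C0")
    ax.barh(t["pathway"], t["nes"], color=colors)
    ax.set_xlabel("NES")
    return ax
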