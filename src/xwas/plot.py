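"""Optional Manhattan-style plot of gene-level association results.

Plotting is non-contractual plumbing; matplotlib is imported lazily so the
rest of the package works without it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan(xwas_table: pd.DataFrame, path, *, alpha: float = 0.05,
              title: str | None = None) -> None:
    """Scatter -log10(asymptotic P) per gene, highlighting permutation hits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = xwas_table.reset_index(drop=True)
    neglog = -np.log10(np.clip(df["p_asymptotic"].to_numpy(), 1e-300, 1.0))
    sig = df["p_perm"].to_numpy() < alpha
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.scatter(df.index[~sig], neglog[~sig], s=8, c="#777777", label=None)
    ax.scatter(df.index[sig], neglog[sig], s=16, c="#c0392b",
               label=f"permutation P < {alpha:g}")
    for i in np.flatnonzero(sig):
        ax.annotate(df["gene_id"].iloc[i], (i, neglog[i]), fontsize=7,
                    xytext=(0, 4), textcoords="offset points", ha="center")
    ax.set_xlabel("gene index")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    if title:
        ax.set_title(title)
    if sig.any():
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
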