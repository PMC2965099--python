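"""Optional rendered diagnostics: Q-Q and Manhattan plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .inference import QqResult

__all__ = ["plot_qq", "plot_manhattan"]


def plot_qq(qq: QqResult, path: str | Path, title: str = "",
            log_scale: bool = True) -> None:
    """Observed vs expected quantiles; the slope line marks the null."""
    fig, ax = plt.subplots(figsize=(4, 4))
    x, y = qq.expected, qq.observed
    if log_scale:
        x = -np.log10(np.maximum(x, 1e-300))
        y = -np.log10(np.maximum(y, 1e-300))
        ax.set_xlabel("expected $-\\log_{10}(p)$")
        ax.set_ylabel("observed $-\\log_{10}(p)$")
    else:
        ax.set_xlabel("expected quantile")
        ax.set_ylabel("observed quantile")
    ax.scatter(x, y, s=4, color="steelblue", rasterized=False)
    lim = max(np.max(x), np.max(y))
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    label = f"inflation = {qq.inflation_factor:.3f}"
    ax.set_title(f"{title} ({label})" if title else label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_manhattan(results: pd.DataFrame, path: str | Path,
                   threshold: float | None = None,
                   title: str = "") -> None:
    """-log10 raw P by genome position from a results frame
    (columns chrom, pos, raw_p), chromosomes in alternating colors."""
    frame = results.copy()
    frame["chrom"] = frame["chrom"].astype(str)
    order = sorted(frame["chrom"].unique(),
                   key=lambda c: (not c.isdigit(),
                                  int(c) if c.isdigit() else 0, c))
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for k, chrom in enumerate(order):
        sub = frame[frame["chrom"] == chrom].sort_values("pos")
        x = offset + sub["pos"].to_numpy()
        ax.scatter(x, -np.log10(np.maximum(sub["raw_p"].to_numpy(),
                                           1e-300)),
                   s=4, color=("steelblue", "darkorange")[k % 2])
        ticks.append(offset + sub["pos"].max() / 2 if len(sub) else offset)
        labels.append(chrom)
        offset += (sub["pos"].max() if len(sub) else 0) + 1
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=1, ls="--")
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("$-\\log_{10}(p)$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
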