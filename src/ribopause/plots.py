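"""SVG plotting helpers (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def scatter_refreq(x: pd.Series, y: pd.Series, path: str | Path,
                   xlabel: str = "relative frequency, set 1 (%)",
                   ylabel: str = "relative frequency, set 2 (%)") -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.scatter(x, y, s=14)
    for label in x.index:
        ax.annotate(str(label), (x[label], y[label]), fontsize=6, alpha=0.7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def heatmap(matrix: pd.DataFrame, path: str | Path, cmap: str = "RdBu_r",
            center: float | None = 1.0) -> None:
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * matrix.shape[1]),
                                    max(2, 0.4 * matrix.shape[0])))
    data = matrix.to_numpy(dtype=float)
    if center is not None:
        span = np.nanmax(np.abs(data - center)) or 1.0
        im = ax.imshow(data, cmap=cmap, vmin=center - span, vmax=center + span,
                       aspect="auto")
    else:
        im = ax.imshow(data, cmap=cmap, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), labels=[str(c) for c in matrix.columns],
                  rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), labels=[str(i) for i in matrix.index],
                  fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
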