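"""Minimal plot helpers for the report bundle (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "",
                 cmap: str = "RdBu_r", vmin=None, vmax=None) -> None:
    """Heatmap of a CpG x tissue matrix (mean beta or genotypic effect)."""
    fig, ax = plt.subplots(figsize=(4 + 0.3 * matrix.shape[1],
                                    1 + 0.25 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto",
                   cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns])
    ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
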