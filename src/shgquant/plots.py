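"""Figure helpers for the pipeline artifacts (headless-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .classifier import ConfusionMatrix  # noqa: E402
from .orientation import FiberAngleSet  # noqa: E402
from .selection import ImportanceRanking  # noqa: E402


def plot_importances(ranking: ImportanceRanking, path: str | Path) -> Path:
    frame = ranking.as_frame()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.barh(frame["feature"][::-1], frame["importance"][::-1], color="#4477aa")
    ax.set_xlabel("mean decrease in Gini impurity")
    ax.set_title("Random-forest feature importances")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_confusion(matrix: ConfusionMatrix, path: str | Path) -> Path:
    grid = np.array([[matrix.tn, matrix.fp], [matrix.fn, matrix.tp]])
    fig, ax = plt.subplots(figsize=(3.6, 3.2))
    ax.imshow(grid, cmap="Blues")
    for (i, j), v in np.ndenumerate(grid):
        ax.text(j, i, str(v), ha="center", va="center",
                color="black" if v < grid.max() * 0.6 else "white")
    ax.set_xticks([0, 1], ["pred 0", "pred 1"])
    ax.set_yticks([0, 1], ["true 0", "true 1"])
    ax.set_title("Aggregated confusion matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_angle_histograms(angle_sets: dict[str, FiberAngleSet],
                          path: str | Path) -> Path:
    n = len(angle_sets)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), squeeze=False)
    for ax, (group, aset) in zip(axes[0], angle_sets.items()):
        centers = 0.5 * (aset.bin_edges[:-1] + aset.bin_edges[1:])
        ax.bar(centers, aset.probabilities,
               width=np.diff(aset.bin_edges), color="#cc6677")
        ax.set_title(f"{group}: width {aset.width:.1f}°")
        ax.set_xlabel("relative angle (°)")
        ax.set_ylabel("probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_cluster_scatter(table: pd.DataFrame, cluster_labels: np.ndarray,
                         feature_triples: list[tuple[str, str, str]],
                         path: str | Path) -> Path:
    """3-D scatter projections of the clustered image features."""
    n = len(feature_triples)
    fig = plt.figure(figsize=(4.2 * n, 3.8))
    for i, (fx, fy, fz) in enumerate(feature_triples, start=1):
        ax = fig.add_subplot(1, n, i, projection="3d")
        for c, color in zip((0, 1), ("#4477aa", "#cc3311")):
            sel = cluster_labels == c
            ax.scatter(table[fx][sel], table[fy][sel], table[fz][sel],
                       s=10, color=color, label=f"cluster {c}")
        ax.set_xlabel(fx)
        ax.set_ylabel(fy)
        ax.set_zlabel(fz)
        ax.legend(loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
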