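"""Optional figure rendering (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

import pathlib
from typing import Mapping, Sequence

import numpy as np

from .evaluate import CLASS_NAMES


def _plt():
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        return plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib "
                          "(pip install cylqa[plot])") from exc


def plot_roc_curves(curves: Mapping[str, tuple[np.ndarray, np.ndarray, float]],
                    out: str | pathlib.Path) -> None:
    """``curves`` maps a label to (fpr, tpr, auc)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, (fpr, tpr, auc) in curves.items():
        ax.plot(fpr, tpr, label=f"{label} (AUC {auc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_confusion(cm: np.ndarray, out: str | pathlib.Path,
                   class_names: Sequence[str] = CLASS_NAMES) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(int(cm[i, j])), ha="center", va="center",
                    color="black" if cm[i, j] < cm.max() / 2 else "white")
    ax.set_xticks(range(len(class_names)), class_names, rotation=45)
    ax.set_yticks(range(len(class_names)), class_names)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_gpr_boxes(summaries: Mapping[str, Mapping[str, Mapping[str, float]]],
                   out: str | pathlib.Path) -> None:
    """Box plots of per-class pass rates, one panel per criterion."""
    plt = _plt()
    criteria = sorted({c for row in summaries.values() for c in row})
    fig, axes = plt.subplots(1, len(criteria),
                             figsize=(3.2 * len(criteria), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, crit in zip(axes, criteria):
        data, labels = [], []
        for cls, row in summaries.items():
            if crit in row and "values" in row[crit]:
                data.append(row[crit]["values"])
                labels.append(cls)
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(crit)
        ax.tick_params(axis="x", rotation=45)
    axes[0].set_ylabel("Gamma pass rate (%)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
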