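"""Optional figure output: confusion-matrix heatmap and ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import EvaluationReport


def plot_confusion(report: EvaluationReport, path: str | Path) -> None:
    """Row-percent heatmap with raw counts in parentheses, rows = true labels."""
    pct = report.confusion.row_percent()
    counts = report.confusion.counts
    classes = report.confusion.classes
    fig, ax = plt.subplots(figsize=(1.4 * len(classes) + 2, 1.2 * len(classes) + 1.5))
    im = ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
    for i in range(len(classes)):
        for j in range(len(classes)):
            ax.text(
                j, i, f"{pct[i, j]:.0f}%\n({counts[i, j]})",
                ha="center", va="center",
                color="white" if pct[i, j] > 50 else "black", fontsize=9,
            )
    ax.set_xticks(range(len(classes)), classes, rotation=30, ha="right")
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted label")
    ax.set_ylabel("true label")
    ax.set_title(f"{report.scheme_name}: accuracy {report.metrics_percent['accuracy']}%")
    fig.colorbar(im, ax=ax, label="% of true label")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(report: EvaluationReport, path: str | Path) -> None:
    """One-vs-rest ROC curve per class with its AUC."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for cls, curve in report.roc.items():
        if curve["auc"] is None:
            continue
        ax.plot(curve["fpr"], curve["tpr"], label=f"{cls} (AUC {curve['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"ROC — {report.scheme_name}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
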