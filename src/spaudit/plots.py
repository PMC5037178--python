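"""Plot rendering for evaluation reports (KDE, correlation scatter, ROC)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import seaborn as sns

from .evaluation import EvaluationReport
from .modifications import ALL_KINDS, MODIFICATION_KINDS
from .scoring import ScoreTable

KIND_PALETTE = dict(zip(ALL_KINDS, sns.color_palette("deep", len(ALL_KINDS))))


def plot_densities(report: EvaluationReport, path: str | Path, class_label: str = "positive") -> None:
    """Overlay the score KDE of every modification kind for one class,
    with a rug of the original scores and the 0.5/0.6 threshold lines."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for curve in report.densities:
        if curve.class_label != class_label:
            continue
        ax.plot(curve.grid, curve.density, label=curve.kind,
                color=KIND_PALETTE.get(curve.kind))
        if curve.kind == "original":
            ax.plot(curve.rug, [-0.05] * len(curve.rug), "|",
                    color="black", markersize=4, alpha=0.3)
    for thr in report.config.get("thresholds", (0.5, 0.6)):
        ax.axvline(thr, linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlim(-0.05, 1.05)
    ax.set_xlabel("prediction score")
    ax.set_ylabel("density")
    ax.set_title(f"Score distributions ({class_label})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlations(
    score_table: ScoreTable,
    labels: Mapping[str, str],
    path: str | Path,
    class_label: str = "positive",
) -> None:
    """Original-vs-modified score scatter, one panel per modification kind."""
    ids = sorted(rid for rid, lab in labels.items() if lab == class_label)
    original = score_table.scores_for("original", ids)
    fig, axes = plt.subplots(1, len(MODIFICATION_KINDS), figsize=(15, 3.2),
                             sharex=True, sharey=True)
    for ax, kind in zip(axes, MODIFICATION_KINDS):
        modified = score_table.scores_for(kind, ids)
        ax.scatter(original, modified, s=8, alpha=0.5,
                   color=KIND_PALETTE.get(kind))
        ax.plot([0, 1], [0, 1], color="grey", linewidth=0.8)
        ax.set_title(kind, fontsize=9)
        ax.set_xlabel("original score")
    axes[0].set_ylabel("modified score")
    fig.suptitle(f"Score correlation ({class_label})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(report: EvaluationReport, path: str | Path) -> None:
    """All per-kind ROC curves with AUC in the legend; operating points of
    the sp_remove curve annotated."""
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for roc in report.rocs:
        ax.plot(roc.fpr, roc.tpr, label=f"{roc.kind} (AUC {roc.auc:.3f})",
                color=KIND_PALETTE.get(roc.kind))
        if roc.kind == "sp_remove":
            for op in roc.operating_points:
                ax.plot(op.fpr, op.tpr, "o", color="black", markersize=4)
                ax.annotate(op.label, (op.fpr, op.tpr), fontsize=7,
                            textcoords="offset points", xytext=(4, -4))
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("ROC: positive vs negative, per modification")
    ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
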