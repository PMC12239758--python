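"""Optional diagnostic plots: mean ROC curves with SD bands, confusion heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import MetricsReport


def plot_report(report: MetricsReport, path: str | Path) -> None:
    """One figure: mean ROC (±SD band) per model and averaged confusion matrices."""
    models = list(report.models.keys())
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))

    ax = axes[0]
    for name in models:
        roc = report.models[name]["mean_roc"]
        fpr = np.array(roc["fpr"])
        tpr = np.array(roc["tpr_mean"])
        sd = np.array(roc["tpr_sd"])
        auc = report.models[name]["fold_mean"]["roc_auc"]["mean"]
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
        ax.fill_between(fpr, np.clip(tpr - sd, 0, 1), np.clip(tpr + sd, 0, 1), alpha=0.15)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"Mean ROC over {report.n_folds} folds")
    ax.legend(fontsize=8)

    ax = axes[1]
    width = 0.8 / len(models)
    keys = ("TP", "FP", "TN", "FN")
    for i, name in enumerate(models):
        cm = report.models[name]["confusion_mean"]
        ax.bar(
            np.arange(4) + i * width,
            [cm[k] for k in keys],
            width=width,
            label=name,
        )
    ax.set_xticks(np.arange(4) + 0.4 - width / 2)
    ax.set_xticklabels(keys)
    ax.set_ylabel("Fold-averaged count")
    ax.set_title("Averaged confusion matrices")
    ax.legend(fontsize=8)

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
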