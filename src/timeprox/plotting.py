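"""Basic Kaplan-Meier and ROC plots (optional, behind the CLI --plots flag)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import KMResult, ROCResult  # noqa: E402


def plot_km(result: KMResult, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in result.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=name)
    if not result.flagged:
        ax.text(0.98, 0.02, f"log-rank p = {result.p_value:.3g}",
                transform=ax.transAxes, ha="right", va="bottom")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(results: list[ROCResult], path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for r in results:
        ax.plot(r.fpr, r.tpr, label=f"{r.feature_id} (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
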