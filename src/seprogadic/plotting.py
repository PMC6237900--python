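"""Optional SVG figures: Kaplan-Meier panels and time-dependent ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .survival import TimeDepROC, km_estimate

__all__ = ["plot_km_groups", "plot_roc"]


def plot_km_groups(time, event, groups, path: str | Path, title: str = "") -> None:
    """Kaplan-Meier step curves, one per group label, written as SVG."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in np.unique(groups):
        mask = groups == g
        kmf = km_estimate(time[mask], event[mask])
        kmf.plot_survival_function(ax=ax, label=f"{g} (n={mask.sum()})", ci_show=False)
    ax.set_xlabel("months")
    ax.set_ylabel("disease-free survival")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_roc(roc: TimeDepROC, path: str | Path, title: str = "") -> None:
    """Time-dependent ROC curve (cutoff-ordered walk) written as SVG."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    fpr = (1.0 - roc.specificity)[::-1]
    ax.plot(fpr, roc.sensitivity[::-1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title or f"AUC = {roc.auc:.3f} at t = {roc.horizon:g}")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
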