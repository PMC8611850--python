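"""Small plotting helpers for fit curves and training-loss curves."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_fit_curve", "plot_loss_curves"]


def plot_fit_curve(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    path: str | Path,
    title: str = "True vs predicted values",
) -> None:
    """True and predicted values of a test sample, side by side."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    idx = np.arange(len(y_true))
    ax.plot(idx, y_true, "o-", color="tab:red", label="true")
    ax.plot(idx, y_pred, "s--", color="tab:blue", label="predicted")
    ax.set_xlabel("test sample")
    ax.set_ylabel("property value")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loss_curves(
    trajectories: Mapping[str, Sequence[float]], path: str | Path
) -> None:
    """Per-epoch training-loss curves of several models on one axis."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for name, losses in trajectories.items():
        ax.plot(np.arange(1, len(losses) + 1), losses, marker=".", label=name)
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
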