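"""Convenience plots for training histories and confusion matrices."""

from __future__ import annotations

import numpy as np

from .evaluate import EvalReport
from .io import AAMI_CLASSES


def plot_history(history: dict, ax=None):
    """Accuracy and loss convergence curves for one training run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(10, 4))
    epochs = np.arange(1, len(history["train_loss"]) + 1)
    ax[0].plot(epochs, history["train_loss"], label="train")
    ax[0].plot(epochs, history["val_loss"], label="validation")
    ax[0].set_xlabel("epoch"); ax[0].set_ylabel("loss"); ax[0].legend()
    ax[1].plot(epochs, history["train_acc"], label="train")
    ax[1].plot(epochs, history["val_acc"], label="validation")
    ax[1].set_xlabel("epoch"); ax[1].set_ylabel("accuracy"); ax[1].legend()
    return ax


def plot_confusion(report: EvalReport, ax=None):
    """Annotated confusion-matrix heatmap (rows true, columns predicted)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    cm = report.cm.counts
    im = ax.imshow(cm, cmap="Blues")
    classes = list(AAMI_CLASSES[: cm.shape[0]])
    ax.set_xticks(range(len(classes)), classes)
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted"); ax.set_ylabel("true")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    color="white" if cm[i, j] > cm.max() / 2 else "black")
    ax.figure.colorbar(im, ax=ax)
    return ax
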