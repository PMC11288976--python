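"""Side-by-side panels: input feature maps, prediction, ground truth."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .enface_features import FeatureStack  # noqa: E402
from .ensemble_model import PredictionResult  # noqa: E402

__all__ = ["plot_prediction_panel"]


def plot_prediction_panel(stack: FeatureStack, result: PredictionResult,
                          gt: Optional[np.ndarray] = None, path=None):
    """One row of feature maps and one row of prediction/ground-truth maps.

    Returns the figure; saves to ``path`` (PNG) when given.
    """
    n_feats = stack.data.shape[0]
    n_cols = max(n_feats, 3 if gt is not None else 2)
    fig, axes = plt.subplots(2, n_cols, figsize=(2.2 * n_cols, 4.8))
    for ax in axes.ravel():
        ax.set_axis_off()
    for i, (feat, chan) in enumerate(zip(stack.features, stack.data)):
        axes[0, i].imshow(chan, cmap="gray", vmin=0, vmax=1)
        axes[0, i].set_title(feat, fontsize=8)
    panels = [("P(atrophy)", result.probabilities[1], "magma"),
              ("prediction", result.mask, "gray")]
    if gt is not None:
        panels.append(("ground truth", gt, "gray"))
    for i, (title, img, cmap) in enumerate(panels):
        axes[1, i].imshow(img, cmap=cmap, vmin=0, vmax=1)
        axes[1, i].set_title(title, fontsize=8)
    fig.suptitle(f"{stack.region} ({stack.laterality})", fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
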