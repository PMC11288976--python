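"""Model/Results interface over the ensemble.

`AtrophyProgressionModel` binds a training cohort (feature stacks + follow-up
atrophy masks, one region and horizon) to an ensemble architecture; ``fit()``
runs the published training recipe and returns an
`AtrophyProgressionResults` carrying the trained network, the loss history,
and evaluation/summary utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .enface_features import FeatureStack, build_feature_stack, get_region, prepare_mask
from .ensemble_model import (ComponentUNetConfig, EnsembleConfig, EnsembleNetwork,
                             PredictionResult, TrainConfig, train)
from .evaluation import EyeScore, grade_components, summarize

__all__ = ["AtrophyProgressionModel", "AtrophyProgressionResults"]


class AtrophyProgressionModel:
    """Predicts the follow-up atrophy mask from baseline en-face feature maps.

    Parameters
    ----------
    stacks, masks : aligned training samples; every stack must share the
        feature tuple and spatial shape, every mask is binary in the same
        frame.
    unet_config : architecture of each component U-Net (one per feature).
    region, horizon : labels recorded with the fit (the stacks themselves
        already encode the region's feature maps).
    """

    def __init__(self, stacks: Sequence[FeatureStack], masks: Sequence[np.ndarray],
                 unet_config: Optional[ComponentUNetConfig] = None,
                 region: str = "", horizon: str = "6mo"):
        if len(stacks) == 0 or len(stacks) != len(masks):
            raise ValueError("need aligned, non-empty stacks and masks")
        feats = tuple(stacks[0].features)
        shape = stacks[0].data.shape
        for s in stacks:
            if tuple(s.features) != feats or s.data.shape != shape:
                raise ValueError("all stacks must share features and shape")
        self.stacks = list(stacks)
        self.masks = [np.asarray(m) for m in masks]
        self.features = feats
        self.region = region or stacks[0].region
        self.horizon = horizon
        if unet_config is None:
            unet_config = ComponentUNetConfig(input_shape=shape[1:])
        elif tuple(unet_config.input_shape) != shape[1:]:
            raise ValueError(f"unet input {unet_config.input_shape} != stack {shape[1:]}")
        self.config = EnsembleConfig(feats, unet_config)

    @classmethod
    def from_eyes(cls, eyes: Sequence, region, horizon: str = "6mo",
                  out_shape: Tuple[int, int] = (128, 128),
                  features: Optional[Sequence[str]] = None,
                  unet_config: Optional[ComponentUNetConfig] = None):
        """Build training data directly from synthetic (or loaded) eyes."""
        region = get_region(region)
        stacks, masks = [], []
        for eye in eyes:
            stacks.append(build_feature_stack(eye.volume, eye.surfaces, region,
                                              out_shape=out_shape, features=features,
                                              eye_id=eye.eye_id))
            masks.append(prepare_mask(eye.mask_for(horizon), eye.laterality, out_shape))
        return cls(stacks, masks, unet_config, region.name, horizon)

    def fit(self, train_config: Optional[TrainConfig] = None,
            verbose: bool = False) -> "AtrophyProgressionResults":
        train_config = train_config or TrainConfig()
        net = EnsembleNetwork(self.config, seed=train_config.seed)
        history = train(net, self.stacks, self.masks, train_config, verbose=verbose)
        return AtrophyProgressionResults(self, net, train_config,
                                         pd.DataFrame(history))


@dataclass
class AtrophyProgressionResults:
    """A fitted ensemble with its training history."""

    model: AtrophyProgressionModel
    network: EnsembleNetwork
    train_config: TrainConfig
    history: pd.DataFrame
    _train_scores: Optional[pd.DataFrame] = field(default=None, repr=False)

    def predict(self, stack: FeatureStack | np.ndarray) -> PredictionResult:
        return self.network.predict(stack)

    def evaluate(self, stacks: Sequence[FeatureStack], masks: Sequence[np.ndarray],
                 eye_ids: Optional[Sequence[str]] = None,
                 configuration: Optional[str] = None) -> List[EyeScore]:
        """Ensemble + per-component scores for a cohort of held-out eyes."""
        if eye_ids is None:
            eye_ids = [getattr(s, "eye_id", "") or f"eye{i:03d}"
                       for i, s in enumerate(stacks)]
        scores: List[EyeScore] = []
        for sid, stack, mask in zip(eye_ids, stacks, masks):
            res = self.predict(stack)
            eye_scores = grade_components(res, mask, eye_id=sid,
                                          region=self.model.region,
                                          horizon=self.model.horizon)
            if configuration:
                for s in eye_scores:
                    if s.configuration == "ensemble":
                        s.configuration = configuration
            scores.extend(eye_scores)
        return scores

    def summary(self) -> str:
        m = self.model
        lines = [
            "Atrophy progression ensemble",
            "=" * 60,
            f"Region:            {m.region}",
            f"Horizon:           {m.horizon}",
            f"Features (n={len(m.features)}):  " + ", ".join(m.features),
            f"Component U-Net:   depth {m.config.unet.depth}, widths "
            f"{m.config.unet.widths}, {m.config.unet.kernel_size}x"
            f"{m.config.unet.kernel_size} kernels, input {m.config.unet.input_shape}",
            f"Parameters:        {self.network.n_parameters():,}",
            f"Training eyes:     {len(m.stacks)}",
            f"Epochs:            {self.train_config.epochs} "
            f"(schedule {self.train_config.lr_schedule})",
            f"Batch size:        {self.train_config.batch_size}, momentum "
            f"{self.train_config.momentum}, weight decay {self.train_config.weight_decay}",
            f"Pixel weights:     region {self.train_config.region_weight}, "
            f"boundary {self.train_config.boundary_weight}",
            f"Loss:              {self.history['loss'].iloc[0]:.4f} (first epoch) -> "
            f"{self.history['loss'].iloc[-1]:.4f} (final)",
            f"Seed:              {self.train_config.seed}",
        ]
        if self._train_scores is not None:
            lines += ["", "Training-cohort medians:", self._train_scores.to_string(index=False)]
        return "\n".join(lines)

    def score_training_cohort(self) -> pd.DataFrame:
        """Median scores on the training cohort (cached into summary())."""
        scores = self.evaluate(self.model.stacks, self.model.masks)
        self._train_scores = summarize(scores)
        return self._train_scores

    def plot_prediction(self, stack: FeatureStack, gt: Optional[np.ndarray] = None,
                        path=None):
        """Panel of the stack's feature maps with the ensemble prediction."""
        from .plotting import plot_prediction_panel
        return plot_prediction_panel(stack, self.predict(stack), gt, path)

    def save(self, path, meta: Optional[dict] = None) -> None:
        from .io import save_checkpoint
        save_checkpoint(path, self.network,
                        {"region": self.model.region, "horizon": self.model.horizon,
                         "seed": self.train_config.seed,
                         "epochs": self.train_config.epochs} | (meta or {}))
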