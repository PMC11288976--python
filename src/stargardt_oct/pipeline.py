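"""End-to-end workflow: simulate -> features -> register -> train -> predict -> evaluate.

A run is driven by a `PipelineConfig` (YAML-serializable, schema version 1)
and writes all artifacts plus a manifest (config + seed + content hashes)
into a run directory; reruns from the same manifest are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enface_features import build_feature_stack, get_region, prepare_mask, resize_map
from .ensemble_model import ComponentUNetConfig, TrainConfig
from .evaluation import summarize, wilcoxon_paired
from .model import AtrophyProgressionModel
from .registration import register_followup
from .synthetic_data import SynthEyeParams, generate_dataset, train_test_split

__all__ = ["PipelineConfig", "run_pipeline", "compare_configs"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    region: str = "EZ-IRPE"
    features: Optional[Tuple[str, ...]] = None   # None -> all allowed for region
    horizons: Tuple[str, ...] = ("6mo", "12mo")
    n_eyes: int = 32
    volume_shape: Tuple[int, int, int] = (96, 128, 48)
    net_shape: Tuple[int, int] = (64, 64)
    unet_depth: int = 3
    unet_widths: Tuple[int, ...] = (8, 16, 32)
    lr_schedule: Tuple[Tuple[int, float], ...] = ((11, 1e-2), (5, 1e-3))
    batch_size: int = 8
    split_ratio: Tuple[int, int] = (3, 1)
    registration: bool = True
    registration_frame: Tuple[int, int] = (256, 256)
    seed: int = 0
    label: str = "all-features"
    schema_version: int = 1

    def __post_init__(self):
        region = get_region(self.region)
        self.region = region.name
        if self.features is not None:
            self.features = tuple(self.features)
            bad = set(self.features) - set(region.allowed_features)
            if bad:
                raise ValueError(
                    f"features {sorted(bad)} are excluded for region {region.name}")
        self.horizons = tuple(self.horizons)
        if not set(self.horizons) <= {"6mo", "12mo"}:
            raise ValueError(f"horizons must be '6mo'/'12mo', got {self.horizons}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("features", "horizons", "volume_shape", "net_shape",
                    "unet_widths", "split_ratio", "registration_frame"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("lr_schedule") is not None:
            d["lr_schedule"] = tuple((int(n), float(lr)) for n, lr in d["lr_schedule"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(
            json.loads(json.dumps(self.to_dict())), sort_keys=False))

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(batch_size=self.batch_size, lr_schedule=self.lr_schedule,
                           seed=seed)

    def unet_config(self) -> ComponentUNetConfig:
        return ComponentUNetConfig(input_shape=self.net_shape, depth=self.unet_depth,
                                   widths=self.unet_widths)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _registered_gt(eye, horizon: str, config: PipelineConfig, rng: np.random.Generator):
    """Route a follow-up mask through the registration frame and back.

    Emulates the follow-up acquisition: the ground-truth mask lives in a
    slightly rotated/scaled/shifted follow-up frame; vessel landmarks carry
    it back onto the baseline en-face frame.  Returns (native-frame mask,
    landmark residual RMSE).
    """
    H, W = config.registration_frame
    nb, na = eye.mask_baseline.shape
    mask_reg = resize_map(eye.mask_for(horizon), (H, W), mode="label")
    pts = eye.landmarks * np.array([(W - 1) / (na - 1), (H - 1) / (nb - 1)])
    # small similarity perturbation: the residual error modes registration fixes
    ang = rng.uniform(-3, 3) * np.pi / 180
    s = rng.uniform(0.97, 1.03)
    t = rng.uniform(-0.02, 0.02, size=2) * (W, H)
    c, si = np.cos(ang), np.sin(ang)
    from .registration import AffineTransform, warp
    T = AffineTransform(np.array([[s * c, -s * si, t[0]], [s * si, s * c, t[1]]]))
    followup_mask = warp(mask_reg, T, mode="label", output_shape=(H, W))
    followup_pts = T.apply(pts)
    _, reg_mask, _, rmse = register_followup(
        followup_mask.astype(np.float64), followup_mask, followup_pts, pts, (H, W))
    native = resize_map(reg_mask, (nb, na), mode="label")
    return native, rmse


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region = get_region(config.region)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2 ** 31)
    sim_seed, split_seed, train_seed, reg_seed = (int(s) for s in seeds)

    eyes = generate_dataset(config.n_eyes, SynthEyeParams(shape=config.volume_shape),
                            seed=sim_seed)
    train_eyes, test_eyes = train_test_split(eyes, config.split_ratio, seed=split_seed)

    all_scores, reg_rows, histories = [], [], {}
    reg_rng = np.random.default_rng(reg_seed)
    for horizon in config.horizons:
        def gt_masks(cohort):
            masks = []
            for eye in cohort:
                if config.registration:
                    native, rmse = _registered_gt(eye, horizon, config, reg_rng)
                    reg_rows.append({"eye_id": eye.eye_id, "horizon": horizon,
                                     "landmark_rmse": rmse})
                else:
                    native = eye.mask_for(horizon)
                masks.append(prepare_mask(native, eye.laterality, config.net_shape))
            return masks

        def stacks_of(cohort):
            return [build_feature_stack(eye.volume, eye.surfaces, region,
                                        out_shape=config.net_shape,
                                        features=config.features, eye_id=eye.eye_id)
                    for eye in cohort]

        model = AtrophyProgressionModel(stacks_of(train_eyes), gt_masks(train_eyes),
                                        config.unet_config(), region.name, horizon)
        result = model.fit(config.train_config(train_seed))
        histories[horizon] = result.history
        result.save(out / f"checkpoint_{horizon}.npz", {"label": config.label})
        scores = result.evaluate(stacks_of(test_eyes), gt_masks(test_eyes),
                                 eye_ids=[e.eye_id for e in test_eyes],
                                 configuration=config.label)
        all_scores.extend(scores)

    scores_df = pd.DataFrame([vars(s) for s in all_scores])
    scores_df.to_csv(out / "scores.csv", index=False)
    summarize(all_scores).to_csv(out / "summary.csv", index=False)
    for horizon, hist in histories.items():
        hist.to_csv(out / f"history_{horizon}.csv", index=False)
    if reg_rows:
        pd.DataFrame(reg_rows).to_csv(out / "registration_rmse.csv", index=False)
    config.to_yaml(out / "config.yaml")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict())),
        "hashes": {p.name: _sha256(p.read_bytes())
                   for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def compare_configs(run_a, run_b, out_path=None) -> pd.DataFrame:
    """Paired Wilcoxon comparison of two runs' ensemble scores.

    Both runs must cover the same eyes and horizons.  Emits one row per
    (horizon, metric) with both runs' medians, n, and the two-sided p-value.
    """
    frames = {}
    for name, run in (("a", run_a), ("b", run_b)):
        df = pd.read_csv(Path(run) / "scores.csv")
        frames[name] = df[~df["configuration"].str.startswith("component:")]
    labels = {k: v["configuration"].iloc[0] for k, v in frames.items()}
    rows = []
    for horizon in sorted(frames["a"]["horizon"].unique()):
        a = frames["a"][frames["a"]["horizon"] == horizon].set_index("eye_id").sort_index()
        b = frames["b"][frames["b"]["horizon"] == horizon].set_index("eye_id").sort_index()
        if list(a.index) != list(b.index):
            raise ValueError(f"runs do not share eyes for horizon {horizon}")
        for metric in ("dice", "pixel_accuracy"):
            rows.append({
                "horizon": horizon, "metric": metric, "n": len(a),
                f"median_{labels['a']}": a[metric].median(),
                f"median_{labels['b']}": b[metric].median(),
                "p_value": wilcoxon_paired(a[metric].to_numpy(), b[metric].to_numpy()),
            })
    report = pd.DataFrame(rows)
    if out_path is not None:
        out_path = Path(out_path)
        report.to_csv(out_path.with_suffix(".csv"), index=False)
        out_path.with_suffix(".json").write_text(
            json.dumps({"labels": labels, "rows": rows}, indent=2, default=float))
    return report
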