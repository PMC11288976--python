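"""File formats: multi-page TIFF volumes, CSV surfaces/landmarks, PNG masks.

Conventions: volumes are written one page per B-scan (page shape depth x
A-scans); surfaces as long-form CSV with 0-based indices; binary masks as
single-channel 0/255 PNG; feature maps as 32-bit float TIFF with an 8-bit
PNG preview; model checkpoints as ``.npz`` with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .enface_features import BOUNDARIES, EnFaceFeatureMap, LayerSurfaces, OctVolume, normalize01
from .registration import AffineTransform

__all__ = [
    "save_volume", "load_volume", "save_surfaces", "load_surfaces",
    "save_mask", "load_mask", "save_landmarks", "load_landmarks",
    "save_landmark_pairs", "load_landmark_pairs",
    "save_feature_map", "load_feature_map",
    "save_transform", "load_transform",
    "save_checkpoint", "load_checkpoint",
]


def save_volume(path, volume: OctVolume) -> None:
    """One TIFF page per B-scan (page = depth x A-scans)."""
    pages = np.ascontiguousarray(volume.data.transpose(2, 0, 1))
    tifffile.imwrite(str(path), pages, metadata={"laterality": volume.laterality})


def load_volume(path, laterality: Optional[str] = None) -> OctVolume:
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        if laterality is None:
            meta = tf.shaped_metadata or []
            laterality = (meta[0].get("laterality", "OS") if meta else "OS")
    return OctVolume(pages.transpose(1, 2, 0), laterality)


def save_surfaces(path, surfaces: LayerSurfaces) -> None:
    nb, na = surfaces.shape
    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    frames = [pd.DataFrame({"boundary": name, "bscan_index": bb.ravel(),
                            "ascan_index": aa.ravel(),
                            "depth": surfaces[name].ravel()})
              for name in BOUNDARIES]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_surfaces(path) -> LayerSurfaces:
    df = pd.read_csv(path)
    grids: Dict[str, np.ndarray] = {}
    nb = int(df["bscan_index"].max()) + 1
    na = int(df["ascan_index"].max()) + 1
    for name, grp in df.groupby("boundary"):
        g = np.full((nb, na), np.nan)
        g[grp["bscan_index"].to_numpy(), grp["ascan_index"].to_numpy()] = grp["depth"].to_numpy()
        grids[name] = g
    return LayerSurfaces(grids)


def save_mask(path, mask: np.ndarray) -> None:
    m = np.asarray(mask)
    if not np.isin(np.unique(m), (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    iio.imwrite(str(path), (m * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    m = np.asarray(iio.imread(str(path)))
    if m.ndim == 3:
        m = m[..., 0]
    return (m > 127).astype(np.uint8)


def save_landmarks(path, points: np.ndarray) -> None:
    """Vessel landmark points in the native en-face frame (x = A-scan, y = B-scan)."""
    pts = np.asarray(points, dtype=np.float64)
    pd.DataFrame({"point_id": np.arange(len(pts)),
                  "ascan_index": pts[:, 0], "bscan_index": pts[:, 1]}).to_csv(path, index=False)


def load_landmarks(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("point_id")
    return df[["ascan_index", "bscan_index"]].to_numpy(dtype=np.float64)


def save_landmark_pairs(path, moving: np.ndarray, fixed: np.ndarray) -> None:
    m = np.asarray(moving, dtype=np.float64)
    f = np.asarray(fixed, dtype=np.float64)
    pd.DataFrame({"moving_x": m[:, 0], "moving_y": m[:, 1],
                  "fixed_x": f[:, 0], "fixed_y": f[:, 1]}).to_csv(path, index=False)


def load_landmark_pairs(path) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df[["moving_x", "moving_y"]].to_numpy(dtype=np.float64),
            df[["fixed_x", "fixed_y"]].to_numpy(dtype=np.float64))


def save_feature_map(path, fmap: EnFaceFeatureMap, preview: bool = True) -> None:
    path = Path(path)
    tifffile.imwrite(str(path), fmap.data.astype(np.float32),
                     metadata={"feature": fmap.feature, "region": fmap.region,
                               "stage": fmap.stage})
    if preview:
        iio.imwrite(str(path.with_suffix(".png")),
                    (normalize01(fmap.data) * 255).astype(np.uint8))


def load_feature_map(path) -> EnFaceFeatureMap:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = (tf.shaped_metadata or [{}])[0]
    return EnFaceFeatureMap(data, meta.get("feature", "unknown"),
                            meta.get("region", "unknown"), meta.get("stage", "native"))


def save_transform(path, transform: AffineTransform) -> None:
    Path(path).write_text(json.dumps({"matrix": transform.matrix.tolist()}, indent=2))


def load_transform(path) -> AffineTransform:
    return AffineTransform(np.asarray(json.loads(Path(path).read_text())["matrix"]))


def save_checkpoint(path, network, meta: Optional[dict] = None) -> None:
    """Weights as .npz plus a JSON sidecar (architecture, features, metadata)."""
    path = Path(path)
    np.savez(path, **network.state_dict())
    cfg = network.config
    sidecar = {
        "features": list(cfg.features),
        "unet": {"input_shape": list(cfg.unet.input_shape),
                 "in_channels": cfg.unet.in_channels,
                 "depth": cfg.unet.depth,
                 "widths": list(cfg.unet.widths),
                 "kernel_size": cfg.unet.kernel_size,
                 "n_classes": cfg.unet.n_classes},
        "n_parameters": network.n_parameters(),
    } | (meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path):
    from .ensemble_model import ComponentUNetConfig, EnsembleConfig, EnsembleNetwork

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    u = sidecar["unet"]
    cfg = EnsembleConfig(tuple(sidecar["features"]),
                         ComponentUNetConfig(tuple(u["input_shape"]), u["in_channels"],
                                             u["depth"], tuple(u["widths"]),
                                             u["kernel_size"], u["n_classes"]))
    net = EnsembleNetwork(cfg, seed=0)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        net.load_state_dict(dict(data))
    return net, sidecar
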