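"""En-face feature maps from OCT volumes and retinal layer surfaces.

An OCT volume is indexed (z: depth, a: A-scan, b: B-scan).  Five segmented
boundary surfaces — ELM, EZ, inner RPE, outer RPE, choroid–sclera junction —
define slab regions; for each en-face position (b, a) the voxels between two
boundaries form a column, and a per-column statistic (mean, median, max, min,
standard deviation, skewness, kurtosis, gray-level entropy) or the slab
thickness yields one pixel of a 2D en-face feature map (rows = B-scans,
cols = A-scans).

Statistic conventions: population (biased) central moments; kurtosis is
non-excess m4/m2^2; skewness and kurtosis are 0 for zero-variance columns;
gray-level entropy is Shannon entropy in bits over the 256 native 8-bit gray
levels.  Column sampling is inclusive over integer depths between the rounded
boundary positions; the symmetric EZ+-5 region spans 5 depth pixels either
side of the rounded EZ position, clamped to the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "BOUNDARIES",
    "CANONICAL_FEATURES",
    "INTENSITY_FEATURES",
    "REGION_NAMES",
    "OctVolume",
    "LayerSurfaces",
    "RegionSpec",
    "EnFaceFeatureMap",
    "FeatureStack",
    "get_region",
    "column_samples",
    "column_statistic",
    "column_thickness",
    "build_feature_map",
    "resize_map",
    "reflect_if_od",
    "normalize01",
    "build_feature_stack",
    "prepare_mask",
]

BOUNDARIES = ("ELM", "EZ", "IRPE", "ORPE", "CS")

# Canonical feature order (ensemble channel order).
CANONICAL_FEATURES = ("mean", "std", "max", "min", "median",
                      "kurtosis", "skewness", "gray_level_entropy", "thickness")
INTENSITY_FEATURES = CANONICAL_FEATURES[:-1]

_GRAY_LEVELS = 256


@dataclass
class OctVolume:
    """3D OCT intensity grid, values on the 8-bit [0, 255] scale.

    ``data`` is indexed (z, a, b): depth, A-scan, B-scan.  ``laterality`` is
    "OD" (right) or "OS" (left); OD en-face maps are mirrored downstream.
    """

    data: np.ndarray
    laterality: str = "OS"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3D (depth, A-scans, B-scans)")
        if not np.isfinite(np.asarray(self.data, dtype=np.float64)).all():
            raise ValueError("volume contains non-finite values")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")

    @property
    def depth(self) -> int:
        return self.data.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.data.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.data.shape[2]


@dataclass
class LayerSurfaces:
    """Axial boundary positions, one (n_bscans, n_ascans) grid per boundary.

    Positions are fractional 0-based depth pixels increasing downward; at
    every (b, a) the boundaries must satisfy ELM <= EZ <= IRPE <= ORPE <= CS.
    """

    surfaces: Dict[str, np.ndarray]

    def __post_init__(self):
        missing = [k for k in BOUNDARIES if k not in self.surfaces]
        if missing:
            raise ValueError(f"missing boundary surfaces: {missing}")
        shapes = {self.surfaces[k].shape for k in BOUNDARIES}
        if len(shapes) != 1:
            raise ValueError(f"boundary grids must share shape, got {shapes}")
        for lo, hi in zip(BOUNDARIES[:-1], BOUNDARIES[1:]):
            if np.any(self.surfaces[lo] > self.surfaces[hi]):
                raise ValueError(f"boundary ordering violated: {lo} above {hi} required")
        if np.any(self.surfaces[BOUNDARIES[0]] < 0):
            raise ValueError("boundary positions must be >= 0")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.surfaces[BOUNDARIES[0]].shape

    def validate_against(self, volume: OctVolume) -> None:
        if self.shape != (volume.n_bscans, volume.n_ascans):
            raise ValueError(
                f"surface grids {self.shape} do not match en-face frame "
                f"{(volume.n_bscans, volume.n_ascans)}")
        if np.any(self.surfaces[BOUNDARIES[-1]] > volume.depth - 1):
            raise ValueError("boundary positions exceed volume depth")


@dataclass(frozen=True)
class RegionSpec:
    """A slab between two boundaries, or a symmetric band about the EZ.

    ``excluded_features`` is exactly {"thickness"} for ORPE-CS (too much
    natural thickness variation) and EZ+-5 (constant by construction), and
    empty otherwise.
    """

    name: str
    inner: Optional[str] = None
    outer: Optional[str] = None
    ez_offset: Optional[int] = None
    excluded_features: frozenset = field(default_factory=frozenset)

    @property
    def allowed_features(self) -> Tuple[str, ...]:
        return tuple(f for f in CANONICAL_FEATURES if f not in self.excluded_features)


_REGIONS: Dict[str, RegionSpec] = {
    "ELM-EZ": RegionSpec("ELM-EZ", "ELM", "EZ"),
    "EZ-IRPE": RegionSpec("EZ-IRPE", "EZ", "IRPE"),
    "IRPE-ORPE": RegionSpec("IRPE-ORPE", "IRPE", "ORPE"),
    "ORPE-CS": RegionSpec("ORPE-CS", "ORPE", "CS",
                          excluded_features=frozenset({"thickness"})),
    "ELM-IRPE": RegionSpec("ELM-IRPE", "ELM", "IRPE"),
    "EZ+-5": RegionSpec("EZ+-5", ez_offset=5,
                        excluded_features=frozenset({"thickness"})),
}
REGION_NAMES = tuple(_REGIONS)

_REGION_ALIASES = {"EZ±5": "EZ+-5", "EZ+/-5": "EZ+-5", "EZPM5": "EZ+-5"}


def get_region(name) -> RegionSpec:
    """Look up a region by name (aliases like 'EZ±5' accepted)."""
    if isinstance(name, RegionSpec):
        return name
    key = _REGION_ALIASES.get(name, _REGION_ALIASES.get(str(name).upper(), name))
    try:
        return _REGIONS[key]
    except KeyError:
        raise KeyError(f"unknown region {name!r}; valid: {REGION_NAMES}") from None


@dataclass
class EnFaceFeatureMap:
    """One 2D en-face statistic map (rows = B-scans, cols = A-scans)."""

    data: np.ndarray
    feature: str
    region: str
    stage: str = "native"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("feature map must be 2D")
        if not np.isfinite(self.data).all():
            raise ValueError("feature map contains non-finite values")


@dataclass
class FeatureStack:
    """Channel-stacked feature maps at network resolution, each in [0, 1]."""

    data: np.ndarray          # (n_features, H, W)
    features: Tuple[str, ...]
    region: str
    laterality: str = "OS"
    eye_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.features):
            raise ValueError("stack data must be (n_features, H, W)")


# ---------------------------------------------------------------------------
# column-level operations


def _rint(x) -> np.ndarray:
    return np.rint(np.asarray(x)).astype(np.int64)


def _column_bounds(surfaces: LayerSurfaces, region: RegionSpec, depth: int):
    """Integer inclusive depth bounds (lo, hi) per column, degeneracy-resolved.

    Returns (lo, hi, degenerate) as (n_bscans, n_ascans) arrays.  A column is
    degenerate when the rounded outer bound falls above the rounded inner
    bound; it is then collapsed to the single voxel at the rounded midpoint.
    """
    if region.ez_offset is not None:
        ez = _rint(surfaces["EZ"])
        lo = np.clip(ez - region.ez_offset, 0, depth - 1)
        hi = np.clip(ez + region.ez_offset, 0, depth - 1)
        return lo, hi, np.zeros(lo.shape, dtype=bool)
    inner = surfaces[region.inner]
    outer = surfaces[region.outer]
    lo, hi = _rint(inner), _rint(outer)
    degenerate = hi < lo
    if degenerate.any():
        mid = _rint((inner + outer) / 2.0)
        lo = np.where(degenerate, mid, lo)
        hi = np.where(degenerate, mid, hi)
    return lo, hi, degenerate


def column_samples(volume: OctVolume, surfaces: LayerSurfaces, region,
                   b: int, a: int) -> np.ndarray:
    """Voxel intensities of one (b, a) column between the region boundaries.

    Samples integer depths z in [round(inner), round(outer)] inclusive; for
    EZ+-5, z in [round(EZ)-5, round(EZ)+5] clamped to the volume.  A column
    whose rounded outer bound lies above its rounded inner bound collapses to
    the single voxel at the rounded midpoint.
    """
    region = get_region(region)
    if not (0 <= b < volume.n_bscans and 0 <= a < volume.n_ascans):
        raise IndexError(f"column ({b}, {a}) out of range")
    lo, hi, _ = _column_bounds(surfaces, region, volume.depth)
    return np.asarray(volume.data[lo[b, a]:hi[b, a] + 1, a, b], dtype=np.float64)


def column_statistic(values: Sequence[float], feature: str,
                     n_gray_levels: int = _GRAY_LEVELS) -> float:
    """One summary statistic of a column of intensities (not thickness)."""
    if feature == "thickness":
        raise ValueError("thickness is a surface-derived feature; use column_thickness")
    if feature not in INTENSITY_FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty column")
    if not np.isfinite(v).all():
        raise ValueError("non-finite intensity in column")
    if feature == "mean":
        return float(v.mean())
    if feature == "median":
        return float(np.median(v))
    if feature == "max":
        return float(v.max())
    if feature == "min":
        return float(v.min())
    if feature == "gray_level_entropy":
        counts = np.bincount(np.clip(_rint(v), 0, n_gray_levels - 1),
                             minlength=n_gray_levels)
        p = counts[counts > 0] / v.size
        return float(-(p * np.log2(p)).sum())
    m = v.mean()
    d = v - m
    m2 = float((d * d).mean())
    if feature == "std":
        return float(np.sqrt(m2))
    if m2 == 0.0:
        return 0.0
    if feature == "skewness":
        return float((d ** 3).mean() / m2 ** 1.5)
    # kurtosis, non-excess
    return float((d ** 4).mean() / m2 ** 2)


def column_thickness(surfaces: LayerSurfaces, region, b: int, a: int) -> float:
    """Slab thickness outer(b,a) - inner(b,a) in continuous depth pixels."""
    region = get_region(region)
    if "thickness" in region.excluded_features:
        raise ValueError(
            f"thickness is excluded for region {region.name}: too much natural "
            "variation (ORPE-CS) or constant by construction (EZ+-5)")
    return float(surfaces[region.outer][b, a] - surfaces[region.inner][b, a])


# ---------------------------------------------------------------------------
# map-level operations


def _column_histograms(volume: OctVolume, surfaces: LayerSurfaces,
                       region: RegionSpec) -> np.ndarray:
    """(n_bscans, n_ascans, 256) per-column gray-level counts (uint8 volumes)."""
    nb, na = volume.n_bscans, volume.n_ascans
    lo, hi, _ = _column_bounds(surfaces, region, volume.depth)
    zz = np.arange(volume.depth)[:, None, None]
    mask = (zz >= lo.T[None]) & (zz <= hi.T[None])        # (depth, a, b)
    vals = np.asarray(volume.data, dtype=np.int64)[mask]
    ids = np.broadcast_to((np.arange(nb)[None, :] * na
                           + np.arange(na)[:, None])[None], mask.shape)[mask]
    hist = np.bincount(ids * _GRAY_LEVELS + vals,
                       minlength=nb * na * _GRAY_LEVELS)
    return hist.reshape(nb, na, _GRAY_LEVELS)


def _stats_from_histograms(hist: np.ndarray, feature: str) -> np.ndarray:
    levels = np.arange(_GRAY_LEVELS, dtype=np.float64)
    n = hist.sum(axis=-1)
    if feature == "min":
        return ((hist > 0).argmax(axis=-1)).astype(np.float64)
    if feature == "max":
        return (_GRAY_LEVELS - 1 - (hist > 0)[..., ::-1].argmax(axis=-1)).astype(np.float64)
    if feature == "median":
        c = hist.cumsum(axis=-1)
        k_lo = (c > ((n - 1) // 2)[..., None]).argmax(axis=-1)
        k_hi = (c > (n // 2)[..., None]).argmax(axis=-1)
        return (k_lo + k_hi) / 2.0
    if feature == "gray_level_entropy":
        p = hist / n[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return t.sum(axis=-1)
    mean = (hist @ levels) / n
    if feature == "mean":
        return mean
    dev = levels[None, None, :] - mean[..., None]
    hf = hist.astype(np.float64)
    m2 = (hf * dev ** 2).sum(axis=-1) / n
    if feature == "std":
        return np.sqrt(m2)
    safe_m2 = np.where(m2 > 0, m2, 1.0)
    if feature == "skewness":
        m3 = (hf * dev ** 3).sum(axis=-1) / n
        return np.where(m2 > 0, m3 / safe_m2 ** 1.5, 0.0)
    if feature == "kurtosis":
        m4 = (hf * dev ** 4).sum(axis=-1) / n
        return np.where(m2 > 0, m4 / safe_m2 ** 2, 0.0)
    raise ValueError(f"unknown feature {feature!r}")


def build_feature_map(volume: OctVolume, surfaces: LayerSurfaces, region,
                      feature: str) -> EnFaceFeatureMap:
    """Native-resolution en-face map: one statistic per (b, a) column."""
    region = get_region(region)
    surfaces.validate_against(volume)
    if feature == "thickness":
        if "thickness" in region.excluded_features:
            raise ValueError(
                f"thickness is excluded for region {region.name}")
        data = (surfaces[region.outer] - surfaces[region.inner]).astype(np.float64)
        return EnFaceFeatureMap(data, feature, region.name)
    if feature not in INTENSITY_FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    if np.issubdtype(np.asarray(volume.data).dtype, np.integer):
        hist = _column_histograms(volume, surfaces, region)
        data = _stats_from_histograms(hist, feature)
    else:
        nb, na = volume.n_bscans, volume.n_ascans
        data = np.empty((nb, na), dtype=np.float64)
        for b in range(nb):
            for a in range(na):
                data[b, a] = column_statistic(
                    column_samples(volume, surfaces, region, b, a), feature)
    return EnFaceFeatureMap(data, feature, region.name)


def resize_map(image: np.ndarray, shape: Tuple[int, int], mode: str = "continuous") -> np.ndarray:
    """Resize an en-face map: bilinear for continuous data, nearest for labels.

    Aspect ratio is not preserved (native 49 x n_ascans frames map onto square
    registration/network frames).
    """
    img = np.asarray(image)
    if min(shape) < 2:
        raise ValueError("target dims must be >= 2")
    if mode == "continuous":
        return _sk_resize(img.astype(np.float64), shape, order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
    if mode == "label":
        uniq = np.unique(img)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("label-mode resize requires a binary (0/1) input")
        out = _sk_resize(img.astype(np.float64), shape, order=0, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        return out.astype(img.dtype)
    raise ValueError(f"unknown resize mode {mode!r}")


def reflect_if_od(image: np.ndarray, laterality: str) -> np.ndarray:
    """Mirror OD (right-eye) maps along the A-scan axis; OS maps pass through."""
    if laterality == "OD":
        return np.asarray(image)[:, ::-1].copy()
    if laterality == "OS":
        return np.asarray(image)
    raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")


def normalize01(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant maps become all-zero."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def build_feature_stack(volume: OctVolume, surfaces: LayerSurfaces, region,
                        out_shape: Tuple[int, int] = (128, 128),
                        features: Optional[Sequence[str]] = None,
                        eye_id: str = "") -> FeatureStack:
    """All feature maps of a region, OD-reflected, resized, normalized to [0,1].

    Channels follow the canonical feature order (thickness absent for ORPE-CS
    and EZ+-5); requesting an excluded feature raises.
    """
    region = get_region(region)
    if features is None:
        features = region.allowed_features
    else:
        features = tuple(features)
        bad = set(features) - set(region.allowed_features)
        if bad:
            raise ValueError(f"features {sorted(bad)} not allowed for region {region.name}")
        features = tuple(f for f in CANONICAL_FEATURES if f in features)
    channels = []
    for feat in features:
        fmap = build_feature_map(volume, surfaces, region, feat).data
        fmap = reflect_if_od(fmap, volume.laterality)
        fmap = resize_map(fmap, out_shape, mode="continuous")
        channels.append(normalize01(fmap))
    return FeatureStack(np.stack(channels).astype(np.float32), features,
                        region.name, volume.laterality, eye_id)


def prepare_mask(mask: np.ndarray, laterality: str,
                 out_shape: Tuple[int, int]) -> np.ndarray:
    """Bring a native-frame binary mask to the network frame (reflect + nearest)."""
    m = reflect_if_od(np.asarray(mask).astype(np.uint8), laterality)
    return resize_map(m, out_shape, mode="label")
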