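"""Synthetic layered OCT volumes with progressive atrophic lesions.

Emulates the data the progression-prediction method consumes: an 8-bit OCT
volume with ordered retinal boundary surfaces (ELM, EZ, inner/outer RPE,
choroid–sclera junction), retinal vessels casting dark axial shadows (usable
as registration landmarks), and a contiguous, central, roughly elliptical
atrophic lesion that grows from baseline through 6-month and 12-month visits.

Disease signal inside the lesion: the EZ–ORPE slab is attenuated, the
sub-RPE slab shows hypertransmission (brighter signal under atrophic RPE),
the EZ–IRPE slab thins, and speckle variance rises.  A "penumbra" applies
those effects at reduced strength over the rings the lesion will grow into,
so baseline scans carry (weaker, mostly higher-order-statistic) signal about
the future lesion extent — the premise that makes progression prediction
from baseline feature maps learnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .enface_features import LayerSurfaces, OctVolume

__all__ = ["SynthEyeParams", "SynthEye", "generate_eye", "generate_dataset",
           "train_test_split"]

_LAYER_MEAN_DEFAULTS = {
    "vitreous": 28.0,    # above ELM (inner retina collapsed into one slab)
    "ELM-EZ": 110.0,
    "EZ-IRPE": 150.0,
    "IRPE-ORPE": 185.0,
    "ORPE-CS": 90.0,     # choroid
    "sclera": 45.0,      # below C-S junction
}

# boundary base depths as fractions of the volume depth
_BOUNDARY_FRACTIONS = {"ELM": 0.40, "EZ": 0.47, "IRPE": 0.55, "ORPE": 0.62, "CS": 0.80}


@dataclass
class SynthEyeParams:
    """Parameters of one synthetic eye.  All intensities are on [0, 255]."""

    shape: Tuple[int, int, int] = (128, 256, 49)   # (depth, n_ascans, n_bscans)
    layer_means: dict = field(default_factory=lambda: dict(_LAYER_MEAN_DEFAULTS))
    noise_sd: float = 12.0
    undulation_amplitude: float = 2.0               # smooth boundary undulation, px
    lesion_center: Optional[Tuple[float, float]] = None   # (a, b) en-face px
    lesion_semi_axes: Optional[Tuple[float, float]] = None  # (sa, sb) en-face px
    growth_factors: Tuple[float, float] = (1.25, 1.5)     # 6-month, 12-month
    attenuation: float = 0.5            # EZ-ORPE intensity loss fraction in [0,1]
    hypertransmission_gain: float = 1.7  # sub-RPE brightening factor >= 1
    thinning: float = 0.5               # EZ-IRPE thickness loss fraction in [0,1]
    noise_gain: float = 2.2             # speckle-variance factor inside lesion
    penumbra: Tuple[float, float] = (0.55, 0.3)  # effect strength in 6/12-month rings
    boundary_jitter: float = 0.06       # lesion outline harmonic jitter amplitude
    n_vessels: int = 6
    vessel_attenuation: float = 0.45    # shadow depth (fraction of signal lost)
    with_hole: bool = False
    with_satellite: bool = False
    laterality: str = "OS"
    seed: int = 0

    def validate(self) -> None:
        d, na, nb = self.shape
        if d < 32 or na < 64 or nb < 8:
            raise ValueError(f"grid dims must be >= (32, 64, 8), got {self.shape}")
        g6, g12 = self.growth_factors
        if not (g12 >= g6 >= 1.0):
            raise ValueError(f"growth factors must satisfy 12mo >= 6mo >= 1, got {self.growth_factors}")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation fraction must be in [0, 1]")
        if self.hypertransmission_gain < 1.0:
            raise ValueError("hypertransmission gain must be >= 1")
        if not 0.0 <= self.thinning <= 1.0:
            raise ValueError("thinning fraction must be in [0, 1]")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")


@dataclass
class SynthEye:
    """One synthetic eye: volume, surfaces, visit masks, vessel landmarks."""

    volume: OctVolume
    surfaces: LayerSurfaces
    mask_baseline: np.ndarray    # (n_bscans, n_ascans) uint8 {0,1}
    mask_6mo: np.ndarray
    mask_12mo: np.ndarray
    landmarks: np.ndarray        # (n_points, 2) float (x=a, y=b), native frame
    laterality: str
    params: SynthEyeParams
    eye_id: str = ""

    def mask_for(self, horizon: str) -> np.ndarray:
        return {"baseline": self.mask_baseline, "6mo": self.mask_6mo,
                "12mo": self.mask_12mo}[horizon]


def _smooth_field(rng: np.random.Generator, nb: int, na: int,
                  amplitude: float, n_waves: int = 3) -> np.ndarray:
    """Sum of random-phase low-frequency sinusoids over the en-face frame."""
    aa = np.arange(na) / na
    bb = np.arange(nb) / nb
    out = np.zeros((nb, na))
    for _ in range(n_waves):
        fa, fb = rng.uniform(0.5, 2.5, size=2)
        pa, pb = rng.uniform(0, 2 * np.pi, size=2)
        w = rng.uniform(0.3, 1.0)
        out += w * np.sin(2 * np.pi * fa * aa[None, :] + pa) \
                 * np.sin(2 * np.pi * fb * bb[:, None] + pb)
    scale = np.abs(out).max()
    return amplitude * out / scale if scale > 0 else out


def _lesion_radius(params: SynthEyeParams, rng: np.random.Generator,
                   nb: int, na: int):
    """Normalized elliptical radius rho(b, a) with smooth angular jitter."""
    ca, cb = params.lesion_center
    sa, sb = params.lesion_semi_axes
    aa = (np.arange(na)[None, :] - ca) / sa
    bb = (np.arange(nb)[:, None] - cb) / sb
    theta = np.arctan2(np.broadcast_to(bb, (nb, na)), np.broadcast_to(aa, (nb, na)))
    rmod = np.ones((nb, na))
    for h in (2, 3, 4):
        c, phi = rng.uniform(0.3, 1.0), rng.uniform(0, 2 * np.pi)
        rmod += params.boundary_jitter * c * np.cos(h * theta + phi)
    rho = np.sqrt(aa ** 2 + bb ** 2) / rmod
    return rho, rmod.max()


def generate_eye(params: SynthEyeParams, eye_id: str = "") -> SynthEye:
    """Generate one synthetic eye, deterministic for a fixed seed."""
    params.validate()
    depth, na, nb = params.shape
    rng = np.random.default_rng(params.seed)

    p = params
    if p.lesion_center is None or p.lesion_semi_axes is None:
        p = replace(p,
                    lesion_center=p.lesion_center or (na / 2.0, nb / 2.0),
                    lesion_semi_axes=p.lesion_semi_axes or (0.16 * na, 0.20 * nb))

    rho, rmod_max = _lesion_radius(p, rng, nb, na)
    g6, g12 = p.growth_factors
    ca, cb = p.lesion_center
    sa, sb = p.lesion_semi_axes
    reach_a, reach_b = sa * g12 * rmod_max, sb * g12 * rmod_max
    if (ca - reach_a < 0 or ca + reach_a > na - 1
            or cb - reach_b < 0 or cb + reach_b > nb - 1):
        raise ValueError(
            f"lesion semi-axes {p.lesion_semi_axes} with growth {g12} exceed the "
            f"{nb}x{na} en-face frame from center {p.lesion_center}")

    mask_b = rho <= 1.0
    mask_6 = rho <= g6
    mask_12 = rho <= g12
    if p.with_hole:
        hole = rho <= 0.35
        mask_b, mask_6, mask_12 = (m & ~hole for m in (mask_b, mask_6, mask_12))
    if p.with_satellite:
        ssa = 0.25 * sa
        right, left = ca + 1.6 * reach_a, ca - 1.6 * reach_a
        sca = right if right + ssa < na - 1 else left
        sca = float(np.clip(sca, ssa + 1, na - 2 - ssa))
        aa = (np.arange(na)[None, :] - sca) / ssa
        bb = (np.arange(nb)[:, None] - cb) / (0.25 * sb)
        sat = aa ** 2 + bb ** 2 <= 1.0
        mask_b, mask_6, mask_12 = mask_b | sat, mask_6 | sat, mask_12 | sat

    # effect strength: full in the baseline lesion, reduced in the growth rings
    s6, s12 = p.penumbra
    effect = np.zeros((nb, na))
    effect[mask_12] = s12
    effect[mask_6] = s6
    effect[mask_b] = 1.0

    # ordered boundary surfaces: ELM + strictly positive gaps
    base = {k: f * depth for k, f in _BOUNDARY_FRACTIONS.items()}
    tilt = _smooth_field(rng, nb, na, p.undulation_amplitude)
    elm = base["ELM"] + tilt
    surf = {"ELM": elm}
    prev_name, prev = "ELM", elm
    for name in ("EZ", "IRPE", "ORPE", "CS"):
        gap = base[name] - base[prev_name]
        wiggle = _smooth_field(rng, nb, na, 0.25 * p.undulation_amplitude)
        prev = prev + np.clip(gap + wiggle, 0.5, None)
        surf[name] = prev
        prev_name = name
    # disease: EZ-IRPE thinning inside the lesion support
    surf["IRPE"] = surf["EZ"] + (surf["IRPE"] - surf["EZ"]) * (1.0 - p.thinning * effect)
    for k in surf:
        surf[k] = np.clip(surf[k], 1.0, depth - 2.0)
    surfaces = LayerSurfaces(surf)

    # vessels: smooth en-face curves along the A-scan axis, casting shadows
    shadow = np.ones((nb, na))
    landmarks = []
    tt = np.arange(na)
    for _ in range(max(p.n_vessels, 3)):
        b0 = rng.uniform(0.1 * nb, 0.9 * nb)
        amp = rng.uniform(0.05, 0.22) * nb
        freq = rng.uniform(0.5, 1.6)
        phase = rng.uniform(0, 2 * np.pi)
        slope = rng.uniform(-0.1, 0.1) * nb / na
        bc = b0 + amp * np.sin(2 * np.pi * freq * tt / na + phase) + slope * tt
        width = rng.uniform(0.9, 1.8)
        prof = np.exp(-0.5 * ((np.arange(nb)[:, None] - bc[None, :]) / width) ** 2)
        shadow *= 1.0 - p.vessel_attenuation * prof
        for frac in (0.25, 0.75):
            a_pt = frac * (na - 1) + rng.uniform(-2, 2)
            idx = int(np.clip(round(a_pt), 0, na - 1))
            b_pt = float(np.clip(bc[idx], 0, nb - 1))
            landmarks.append((float(np.clip(a_pt, 0, na - 1)), b_pt))
    landmarks = np.asarray(landmarks, dtype=np.float64)

    # assemble the volume (z, a, b); per-column fields transposed to (a, b)
    zz = np.arange(depth)[:, None, None]
    sT = {k: v.T[None, :, :] for k, v in surf.items()}
    eT = effect.T[None, :, :]
    vT = shadow.T[None, :, :]

    lm = p.layer_means
    mean_img = np.select(
        [zz < sT["ELM"], zz < sT["EZ"], zz < sT["IRPE"], zz < sT["ORPE"], zz < sT["CS"]],
        [lm["vitreous"], lm["ELM-EZ"], lm["EZ-IRPE"], lm["IRPE-ORPE"], lm["ORPE-CS"]],
        default=lm["sclera"]).astype(np.float64)

    outer_slab = (zz >= sT["EZ"]) & (zz < sT["ORPE"])
    sub_rpe = (zz >= sT["ORPE"]) & (zz < sT["CS"])
    mean_img = np.where(outer_slab, mean_img * (1.0 - p.attenuation * eT), mean_img)
    mean_img = np.where(sub_rpe, mean_img * (1.0 + (p.hypertransmission_gain - 1.0) * eT),
                        mean_img)
    mean_img = np.where(zz >= sT["ELM"], mean_img * vT, mean_img)

    sd_img = np.where(outer_slab | sub_rpe,
                      p.noise_sd * (1.0 + (p.noise_gain - 1.0) * eT), p.noise_sd)
    vol = mean_img + sd_img * rng.standard_normal(mean_img.shape)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    return SynthEye(OctVolume(vol, p.laterality), surfaces,
                    mask_b.astype(np.uint8), mask_6.astype(np.uint8),
                    mask_12.astype(np.uint8), landmarks, p.laterality, p,
                    eye_id=eye_id)


def generate_dataset(n_eyes: int, base_params: Optional[SynthEyeParams] = None,
                     seed: int = 0) -> List[SynthEye]:
    """A cohort of eyes with per-eye parameters jittered deterministically."""
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    base = base_params or SynthEyeParams()
    base.validate()
    depth, na, nb = base.shape
    ss = np.random.SeedSequence(seed)
    eyes = []
    for i, child in enumerate(ss.spawn(n_eyes)):
        eye_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(eye_seed)
        g6 = 1.0 + rng.uniform(0.15, 0.35)
        g12 = g6 + rng.uniform(0.1, 0.3)
        gain = rng.uniform(0.9, 1.1)
        params = replace(
            base,
            lesion_center=(na / 2.0 + rng.uniform(-0.05, 0.05) * na,
                           nb / 2.0 + rng.uniform(-0.05, 0.05) * nb),
            lesion_semi_axes=(0.16 * na * rng.uniform(0.7, 1.15),
                              0.20 * nb * rng.uniform(0.7, 1.15)),
            growth_factors=(g6, g12),
            layer_means={k: v * gain for k, v in base.layer_means.items()},
            noise_sd=base.noise_sd * rng.uniform(0.85, 1.2),
            n_vessels=int(rng.integers(max(3, base.n_vessels - 1), base.n_vessels + 2)),
            laterality="OD" if rng.random() < 0.5 else "OS",
            seed=int(rng.integers(0, 2 ** 31)),
        )
        eyes.append(generate_eye(params, eye_id=f"eye{i:03d}"))
    return eyes


def train_test_split(items: Sequence, ratio: Tuple[int, int] = (3, 1),
                     seed: int = 0) -> Tuple[list, list]:
    """Deterministic shuffled split (default 3:1 train:test)."""
    items = list(items)
    n = len(items)
    n_test = int(round(n * ratio[1] / (ratio[0] + ratio[1])))
    n_test = min(max(n_test, 1), n - 1) if n > 1 else 0
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [items[i] for i in range(n) if i not in test_idx]
    test = [items[i] for i in range(n) if i in test_idx]
    return train, test
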