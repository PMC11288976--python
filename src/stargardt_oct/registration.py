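"""Landmark-based registration of follow-up images to the baseline en-face frame.

Follow-up fundus-autofluorescence images and their ground-truth atrophy masks
are brought into the baseline OCT en-face frame using corresponding vessel
landmarks (branching / bifurcation / crossover points).  The transform family
is affine (2x3), estimated by least squares; a similarity (rotation + uniform
scale + translation) fit is available as an option.  Landmarks are (x, y)
pixel coordinates, x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp as _sk_warp

__all__ = ["AffineTransform", "estimate_affine", "estimate_similarity",
           "warp", "register_followup", "landmark_rmse"]


@dataclass(frozen=True)
class AffineTransform:
    """2x3 matrix mapping moving (x, y, 1) -> fixed (x, y)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if not np.isfinite(m).all():
            raise ValueError("affine matrix has non-finite coefficients")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        A = self.matrix[:, :2]
        t = self.matrix[:, 2]
        Ai = np.linalg.inv(A)
        return AffineTransform(np.hstack([Ai, (-Ai @ t)[:, None]]))

    @property
    def homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return AffineTransform((self.homogeneous @ other.homogeneous)[:2])


def _check_pairs(moving: np.ndarray, fixed: np.ndarray, min_pairs: int = 3):
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 2:
        raise ValueError("landmark pairs must be matching (n, 2) arrays")
    if moving.shape[0] < min_pairs:
        raise ValueError(f"need >= {min_pairs} landmark pairs, got {moving.shape[0]}")
    centered = moving - moving.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(moving).max())) < 2:
        raise ValueError("landmark points are collinear; affine estimation is degenerate")
    return moving, fixed


def estimate_affine(moving: np.ndarray, fixed: np.ndarray) -> AffineTransform:
    """Least-squares affine minimizing sum ||T(moving) - fixed||^2.

    Exactly interpolates three non-collinear pairs; with more pairs returns
    the least-squares fit.
    """
    moving, fixed = _check_pairs(moving, fixed)
    n = moving.shape[0]
    design = np.hstack([moving, np.ones((n, 1))])
    coeffs, *_ = np.linalg.lstsq(design, fixed, rcond=None)
    return AffineTransform(coeffs.T)


def estimate_similarity(moving: np.ndarray, fixed: np.ndarray) -> AffineTransform:
    """Least-squares similarity transform (rotation + uniform scale + shift)."""
    moving, fixed = _check_pairs(moving, fixed, min_pairs=2)
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    X, Y = moving - mc, fixed - fc
    # Umeyama closed form
    cov = Y.T @ X / moving.shape[0]
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    var = (X ** 2).sum() / moving.shape[0]
    s = np.trace(np.diag(S) @ D) / var
    t = fc - s * R @ mc
    return AffineTransform(np.hstack([s * R, t[:, None]]))


def warp(image: np.ndarray, transform: AffineTransform, mode: str = "continuous",
         output_shape: Tuple[int, int] | None = None) -> np.ndarray:
    """Resample ``image`` under ``transform`` (moving -> fixed frame).

    Inverse-mapping resample: the output pixel at fixed-frame position q takes
    the value of the moving image at T^{-1}(q); bilinear for continuous data,
    nearest for label masks; samples outside the frame fill with 0.
    """
    img = np.asarray(image)
    if mode == "label":
        uniq = np.unique(img)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("label-mode warp requires a binary (0/1) image")
        order = 0
    elif mode == "continuous":
        order = 1
    else:
        raise ValueError(f"unknown warp mode {mode!r}")
    # skimage warp's inverse_map takes output (x, y) -> input (x, y)
    sk_inv = _SkAffine(matrix=transform.inverse().homogeneous)
    out = _sk_warp(img.astype(np.float64), sk_inv, order=order, cval=0.0,
                   output_shape=output_shape, preserve_range=True)
    return out.astype(img.dtype) if mode == "label" else out


def landmark_rmse(transform: AffineTransform, moving: np.ndarray,
                  fixed: np.ndarray) -> float:
    """Root-mean-square residual of the fitted landmark correspondences."""
    res = transform.apply(np.asarray(moving, dtype=np.float64)) - np.asarray(fixed, dtype=np.float64)
    return float(np.sqrt((res ** 2).sum(axis=1).mean()))


def register_followup(image: np.ndarray, mask: np.ndarray, moving: np.ndarray,
                      fixed: np.ndarray, output_shape: Tuple[int, int],
                      family: str = "affine"):
    """Register a follow-up image and its mask onto the baseline frame.

    One transform is estimated from the landmark pairs and applied to both
    the image (bilinear) and the mask (nearest).  Returns
    (registered_image, registered_mask, transform, residual_rmse).
    """
    if family == "affine":
        t = estimate_affine(moving, fixed)
    elif family == "similarity":
        t = estimate_similarity(moving, fixed)
    else:
        raise ValueError(f"unknown transform family {family!r}")
    reg_img = warp(image, t, mode="continuous", output_shape=output_shape)
    reg_mask = warp(mask, t, mode="label", output_shape=output_shape)
    return reg_img, reg_mask, t, landmark_rmse(t, moving, fixed)
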