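"""Camera-to-surface space volumes by tetrahedral decomposition, and intake.

The pixels of an ROI are split into unit triangles (each unit pixel square
along its top-left -> bottom-right diagonal).  Back-projecting the three
pixels of a triangle gives the base of a tetrahedron whose apex is the
camera origin; its volume is

    V = s * h / 3,

with s the base-triangle area (half the cross-product magnitude of two edge
vectors) and h the distance from the origin to the base plane
(|p4| / sqrt(p1^2 + p2^2 + p3^2) from the determinant expansion of the plane
through the three vertices).  Summing over all triangles integrates the
volume of space between the camera and the visible surface over the ROI's
view frustum.

Eating lowers the food surface, moving it farther from a top-mounted camera
and *enlarging* the post-meal space volume, so

    intake = space_volume(post) - space_volume(pre)

over the same pre-meal ROI.  Volume hidden behind container walls is
identical in both aligned captures and cancels in the difference — no
container shape knowledge is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .camera import CameraIntrinsics, backproject_roi
from .errors import DimensionMismatchError

logger = logging.getLogger(__name__)

__all__ = [
    "tetra_volume", "triangle_volumes", "triangulate_roi",
    "space_volume", "SpaceVolumeResult", "estimate_intake", "IntakeEstimate",
]


def triangle_volumes(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Tetrahedron volumes (mm^3) for base triangles (p1, p2, p3), apex at origin.

    Vectorized over leading dimensions; degenerate (collinear) bases give 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    v1 = p2 - p1
    v2 = p3 - p1
    cross = np.cross(v1, v2)
    s = 0.5 * np.linalg.norm(cross, axis=-1)
    X1, Y1, Z1 = p1[..., 0], p1[..., 1], p1[..., 2]
    X2, Y2, Z2 = p2[..., 0], p2[..., 1], p2[..., 2]
    X3, Y3, Z3 = p3[..., 0], p3[..., 1], p3[..., 2]
    # plane through the three vertices: n1 x + n2 y + n3 z = n4
    n1 = Y1 * (Z2 - Z3) + Y2 * (Z3 - Z1) + Y3 * (Z1 - Z2)
    n2 = Z1 * (X2 - X3) + Z2 * (X3 - X1) + Z3 * (X1 - X2)
    n3 = X1 * (Y2 - Y3) + X2 * (Y3 - Y1) + X3 * (Y1 - Y2)
    n4 = (X1 * (Y2 * Z3 - Y3 * Z2) + X2 * (Y3 * Z1 - Y1 * Z3)
          + X3 * (Y1 * Z2 - Y2 * Z1))
    norm = np.sqrt(n1 ** 2 + n2 ** 2 + n3 ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(norm > 0, np.abs(n4) / np.where(norm > 0, norm, 1.0), 0.0)
    return s * h / 3.0


def tetra_volume(v1, v2, v3) -> float:
    """Scalar convenience wrapper around :func:`triangle_volumes`."""
    return float(triangle_volumes(np.asarray(v1), np.asarray(v2), np.asarray(v3)))


def triangulate_roi(roi: np.ndarray) -> np.ndarray:
    """Split an ROI into unit pixel triangles.

    Every unit square whose four corner pixels all belong to the ROI is split
    along its top-left -> bottom-right diagonal into two triangles; squares
    touching non-ROI pixels are excluded, so no triangle borrows depth from
    another object across the mask boundary.

    Returns
    -------
    (M, 3, 2) int array of (x, y) pixel coordinates, deterministic order
    (row-major over squares; upper triangle before lower).  An ROI with
    fewer than one complete square yields an empty (0, 3, 2) array.
    """
    roi = np.asarray(roi, dtype=bool)
    ok = roi[:-1, :-1] & roi[:-1, 1:] & roi[1:, :-1] & roi[1:, 1:]
    ys, xs = np.nonzero(ok)
    if len(xs) == 0:
        return np.empty((0, 3, 2), dtype=int)
    # upper: (x,y) (x+1,y) (x+1,y+1); lower: (x,y) (x+1,y+1) (x,y+1)
    upper = np.stack([np.stack([xs, ys], 1),
                      np.stack([xs + 1, ys], 1),
                      np.stack([xs + 1, ys + 1], 1)], axis=1)
    lower = np.stack([np.stack([xs, ys], 1),
                      np.stack([xs + 1, ys + 1], 1),
                      np.stack([xs, ys + 1], 1)], axis=1)
    tris = np.empty((2 * len(xs), 3, 2), dtype=int)
    tris[0::2] = upper
    tris[1::2] = lower
    return tris


@dataclass
class SpaceVolumeResult:
    """Space volume over an ROI: total cm^3, tetrahedron count, skipped pixels."""

    volume_cm3: float
    n_tetrahedra: int
    n_skipped: int


def space_volume(depth: np.ndarray, roi: np.ndarray,
                 intr: CameraIntrinsics) -> SpaceVolumeResult:
    """Volume of space between the camera and the surface seen over an ROI.

    Back-projects the ROI pixels through the pinhole model and sums the
    tetrahedron volumes of the ROI triangulation.  Depth must be corrected:
    an unmeasured pixel inside the ROI raises ``InvalidDepthError``.
    Reported in cm^3 (1 cm^3 = 1000 mm^3).
    """
    roi = np.asarray(roi, dtype=bool)
    pts = backproject_roi(depth, roi, intr)  # validates zeros inside ROI
    tris = triangulate_roi(roi)
    n_roi = int(np.count_nonzero(roi))
    if len(tris) == 0:
        return SpaceVolumeResult(0.0, 0, n_roi)
    p1 = pts[tris[:, 0, 1], tris[:, 0, 0]]
    p2 = pts[tris[:, 1, 1], tris[:, 1, 0]]
    p3 = pts[tris[:, 2, 1], tris[:, 2, 0]]
    total_mm3 = float(triangle_volumes(p1, p2, p3).sum())
    used = np.zeros_like(roi)
    flat = tris.reshape(-1, 2)
    used[flat[:, 1], flat[:, 0]] = True
    n_skipped = n_roi - int(np.count_nonzero(used & roi))
    return SpaceVolumeResult(total_mm3 / 1000.0, len(tris), n_skipped)


@dataclass
class IntakeEstimate:
    """Per-food intake: difference of post- and pre-meal space volumes."""

    region_id: int
    name: str
    pre_cm3: float
    post_cm3: float
    intake_cm3: float
    negative: bool
    n_skipped_pre: int = 0
    n_skipped_post: int = 0


def estimate_intake(pre_depth: np.ndarray,
                    post_depth: np.ndarray,
                    rois: dict[int, np.ndarray],
                    intr: CameraIntrinsics,
                    names: dict[int, str] | None = None) -> list[IntakeEstimate]:
    """Per-food intake amounts from corrected, aligned depth images.

    ``post_depth`` must already be warped into the pre-meal frame and
    compensated; the same pre-meal ROI is applied to both images.  Intake is
    returned signed: a negative value signals alignment or noise problems
    and is logged, never clamped.
    """
    pre_depth = np.asarray(pre_depth, dtype=float)
    post_depth = np.asarray(post_depth, dtype=float)
    if pre_depth.shape != post_depth.shape:
        raise DimensionMismatchError(
            f"pre {pre_depth.shape} and post {post_depth.shape} depth shapes differ")
    names = names or {}
    results = []
    for rid, roi in rois.items():
        if np.asarray(roi).shape != pre_depth.shape:
            raise DimensionMismatchError(
                f"ROI {rid} shape {np.asarray(roi).shape} does not match "
                f"depth {pre_depth.shape}")
        pre = space_volume(pre_depth, roi, intr)
        post = space_volume(post_depth, roi, intr)
        intake = post.volume_cm3 - pre.volume_cm3
        if intake < 0:
            logger.warning("negative intake %.2f cm^3 for region %d — "
                           "possible misalignment or noise", intake, rid)
        results.append(IntakeEstimate(
            region_id=rid, name=names.get(rid, f"region_{rid}"),
            pre_cm3=pre.volume_cm3, post_cm3=post.volume_cm3,
            intake_cm3=intake, negative=intake < 0,
            n_skipped_pre=pre.n_skipped, n_skipped_post=post.n_skipped))
    return results
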