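"""Plate-based registration of pre- and post-meal captures.

The meal plate is (near-)rectangular, so its four corners anchor a plane
homography between the two captures.  Corners come from the minimum-area
enclosing rectangle of the plate mask's convex hull (rotating calipers);
the homography is the exact 4-point solve

    a h = b,   h = a^{-1} b,

an 8x8 linear system in the entries h1..h8 of H (h9 fixed at 1).  The
post-meal color image, depth image, and food masks are all warped with the
same H so plate regions coincide with the pre-meal capture.

Corner correspondence convention: corners are ordered clockwise (in image
coordinates, y down) starting from the corner nearest the image origin, in
both captures; this pairs corners correctly for plate rotations below 45
degrees.  A manual corner override is accepted wherever corners are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint

from .errors import DegenerateRegionError, NonInvertibleError
from .masks import RegionMask

__all__ = [
    "find_plate_corners", "estimate_homography", "apply_homography",
    "warp_image", "inverse_map", "align_post_meal", "AlignmentResult",
]


def _order_corners(corners: np.ndarray) -> np.ndarray:
    """Order 4 corners clockwise (image coords, y down) starting nearest origin."""
    c = np.asarray(corners, dtype=float)
    center = c.mean(axis=0)
    # with y pointing down, increasing atan2 angle sweeps clockwise on screen
    ang = np.arctan2(c[:, 1] - center[1], c[:, 0] - center[0])
    c = c[np.argsort(ang)]
    start = int(np.argmin((c ** 2).sum(axis=1)))
    return np.roll(c, -start, axis=0)


def find_plate_corners(mask: np.ndarray | RegionMask) -> np.ndarray:
    """Four corners of the minimum-area rectangle enclosing a plate mask.

    Rotating calipers over the convex hull of the foreground pixel centers
    yields the minimum-area enclosing rectangle; its four vertices are
    returned as a (4, 2) array of (x, y) pixel coordinates, ordered clockwise
    starting from the vertex nearest the image origin.

    Raises
    ------
    DegenerateRegionError
        For an empty mask or one whose pixels are collinear.
    """
    if isinstance(mask, RegionMask):
        mask = mask.labels > 0
    mask = np.asarray(mask) != 0
    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        raise DegenerateRegionError(f"plate mask has only {len(xs)} foreground pixels")
    pts = MultiPoint(np.column_stack([xs, ys]))
    hull = pts.convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise DegenerateRegionError("plate mask pixels are collinear")
    rect = hull.minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords[:-1], dtype=float)
    return _order_corners(corners)


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Homography H mapping four source points onto four target points.

    Solves the 8x8 system built from the four correspondences (the direct
    linear transform specialized to exactly four points) with a general
    linear solver; H has its bottom-right entry fixed at 1.  Applying H to
    each source point reproduces its target to well below 1e-6 px for
    non-degenerate quadrilaterals.

    Raises
    ------
    NonInvertibleError
        If three of the source or target points are collinear (singular
        system).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (4, 2) or dst.shape != (4, 2):
        raise ValueError("estimate_homography requires exactly four point pairs")
    a = np.zeros((8, 8))
    b = np.zeros(8)
    for k in range(4):
        x, y = src[k]
        u, v = dst[k]
        a[2 * k] = [x, y, 1, 0, 0, 0, -x * u, -y * u]
        a[2 * k + 1] = [0, 0, 0, x, y, 1, -x * v, -y * v]
        b[2 * k] = u
        b[2 * k + 1] = v
    try:
        h = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise NonInvertibleError(f"degenerate point configuration: {exc}") from exc
    H = np.append(h, 1.0).reshape(3, 3)
    if abs(np.linalg.det(H)) < 1e-12:
        raise NonInvertibleError("homography is singular")
    return H


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homography to (N, 2) points (or a single point)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    ones = np.ones((len(pts), 1))
    hom = (H @ np.hstack([pts, ones]).T).T
    return hom[:, :2] / hom[:, 2:3]


def inverse_map(H: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Source coordinates (x, y) that each output pixel of `shape` maps from.

    The warp is an inverse mapping: output pixel (x~, y~) samples the source
    image at H^{-1}(x~, y~).  Returns float arrays (src_x, src_y) of `shape`.
    """
    Hinv = np.linalg.inv(H)
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    denom = Hinv[2, 0] * xs + Hinv[2, 1] * ys + Hinv[2, 2]
    src_x = (Hinv[0, 0] * xs + Hinv[0, 1] * ys + Hinv[0, 2]) / denom
    src_y = (Hinv[1, 0] * xs + Hinv[1, 1] * ys + Hinv[1, 2]) / denom
    return src_x, src_y


def warp_image(img: np.ndarray, H: np.ndarray, *, method: str = "nearest",
               out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Warp an image by homography H (inverse mapping).

    ``method='nearest'`` is mandatory for depth and label images — bilinear
    interpolation across a depth discontinuity would fabricate surfaces that
    exist in neither capture.  ``method='bilinear'`` suits color images.
    Output pixels mapping outside the source are 0 (depth/labels) or black.
    """
    img = np.asarray(img)
    shape = out_shape or img.shape[:2]
    src_x, src_y = inverse_map(H, shape)
    h, w = img.shape[:2]
    if method == "nearest":
        ix = np.rint(src_x).astype(int)
        iy = np.rint(src_y).astype(int)
        valid = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        out = np.zeros(shape + img.shape[2:], dtype=img.dtype)
        out[valid] = img[iy[valid], ix[valid]]
        return out
    if method == "bilinear":
        coords = np.stack([src_y, src_x])
        if img.ndim == 2:
            return ndimage.map_coordinates(img.astype(float), coords, order=1, cval=0.0)
        chans = [ndimage.map_coordinates(img[..., c].astype(float), coords, order=1, cval=0.0)
                 for c in range(img.shape[2])]
        return np.stack(chans, axis=-1)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class AlignmentResult:
    """Post-meal images warped into the pre-meal frame, plus the homography."""

    H: np.ndarray
    color: np.ndarray | None
    depth: np.ndarray | None
    food_masks: RegionMask | None
    plate_mask: np.ndarray
    pre_corners: np.ndarray
    post_corners: np.ndarray


def align_post_meal(pre_plate_mask: np.ndarray,
                    post_plate_mask: np.ndarray,
                    post_color: np.ndarray | None = None,
                    post_depth: np.ndarray | None = None,
                    post_food_masks: RegionMask | None = None,
                    *,
                    pre_corners: np.ndarray | None = None,
                    post_corners: np.ndarray | None = None) -> AlignmentResult:
    """Warp the post-meal capture so its plate coincides with the pre-meal one.

    H maps post-meal plate corners onto pre-meal plate corners (correspondence
    by the shared clockwise ordering).  Color is warped bilinearly, depth and
    label masks nearest-neighbor, all with the same H.  ``pre_corners`` /
    ``post_corners`` override automatic corner detection.
    """
    if pre_corners is None:
        pre_corners = find_plate_corners(pre_plate_mask)
    else:
        pre_corners = _order_corners(pre_corners)
    if post_corners is None:
        post_corners = find_plate_corners(post_plate_mask)
    else:
        post_corners = _order_corners(post_corners)
    H = estimate_homography(post_corners, pre_corners)
    out_shape = np.asarray(pre_plate_mask).shape[:2]
    warped_color = (warp_image(post_color, H, method="bilinear", out_shape=out_shape)
                    if post_color is not None else None)
    warped_depth = (warp_image(post_depth, H, method="nearest", out_shape=out_shape)
                    if post_depth is not None else None)
    warped_masks = None
    if post_food_masks is not None:
        warped_masks = RegionMask(
            warp_image(post_food_masks.labels, H, method="nearest", out_shape=out_shape),
            dict(post_food_masks.names))
    warped_plate = warp_image((np.asarray(post_plate_mask) != 0).astype(np.uint8),
                              H, method="nearest", out_shape=out_shape).astype(bool)
    return AlignmentResult(H=H, color=warped_color, depth=warped_depth,
                           food_masks=warped_masks, plate_mask=warped_plate,
                           pre_corners=pre_corners, post_corners=post_corners)
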