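"""Pinhole camera model: back-projection of depth pixels to 3D points.

A depth image stores, per pixel, the distance in millimeters from the camera
to the first surface along the capture direction (the camera's Z axis); 0
marks an unmeasured pixel.  With focal length ``f`` (pixel units) and optical
center ``(cx, cy)``, a pixel ``(x, y)`` with depth ``d`` back-projects to

    X = d * (x - cx) / f,   Y = d * (y - cy) / f,   Z = d,

the inverse of the perspective projection ``x = f*X/Z + cx``,
``y = f*Y/Z + cy``.

Pixel convention: 0-based, ``x`` = column, ``y`` = row, pixel centers at
integer coordinates.  Depths are mm; the volume engine reports cm^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import DimensionMismatchError, InvalidDepthError

__all__ = ["CameraIntrinsics", "backproject", "project", "backproject_grid", "backproject_roi"]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Intrinsic parameters of a pinhole camera.

    Parameters
    ----------
    f : float
        Focal length in pixel units (single value; square pixels assumed).
    cx, cy : float
        Optical center column / row in pixels.  May differ from the image
        center.
    width, height : int
        Image dimensions in pixels.
    """

    f: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError(f"focal length must be positive, got {self.f}")
        if not (0 <= self.cx < self.width):
            raise ValueError(f"cx={self.cx} outside [0, {self.width})")
        if not (0 <= self.cy < self.height):
            raise ValueError(f"cy={self.cy} outside [0, {self.height})")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) — numpy array shape of matching images."""
        return (self.height, self.width)

    @classmethod
    def from_file(cls, path: str | Path) -> "CameraIntrinsics":
        """Load intrinsics from a YAML or JSON file with keys f, cx, cy, width, height."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(
            f=float(data["f"]),
            cx=float(data["cx"]),
            cy=float(data["cy"]),
            width=int(data["width"]),
            height=int(data["height"]),
        )

    def to_dict(self) -> dict:
        return {"f": self.f, "cx": self.cx, "cy": self.cy,
                "width": self.width, "height": self.height}


def backproject(pixel: tuple[float, float], depth: float,
                intr: CameraIntrinsics) -> np.ndarray:
    """Back-project a single pixel with known depth to a 3D point (mm).

    Returns ``array([X, Y, Z])`` with the camera at the origin and Z along
    the capture direction.

    Raises
    ------
    InvalidDepthError
        If ``depth <= 0`` (0 encodes an unmeasured pixel).
    """
    if depth <= 0:
        raise InvalidDepthError(f"depth must be positive, got {depth}")
    x, y = pixel
    return np.array([depth * (x - intr.cx) / intr.f,
                     depth * (y - intr.cy) / intr.f,
                     float(depth)])


def project(point: np.ndarray, intr: CameraIntrinsics) -> tuple[float, float]:
    """Perspective-project a 3D point (mm) to pixel coordinates (x, y)."""
    X, Y, Z = point
    if Z <= 0:
        raise InvalidDepthError(f"point must lie in front of the camera, Z={Z}")
    return (intr.f * X / Z + intr.cx, intr.f * Y / Z + intr.cy)


def backproject_grid(depth: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Back-project every pixel of a depth image.

    Returns an ``(H, W, 3)`` array of 3D points in mm, grid-aligned with the
    image so pixel neighbor relations are preserved.  Pixels with depth 0
    back-project to (0, 0, 0); callers that care must mask them.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.shape != intr.shape:
        raise DimensionMismatchError(
            f"depth shape {depth.shape} does not match intrinsics {intr.shape}")
    ys, xs = np.mgrid[0:intr.height, 0:intr.width]
    pts = np.empty(depth.shape + (3,), dtype=float)
    pts[..., 0] = depth * (xs - intr.cx) / intr.f
    pts[..., 1] = depth * (ys - intr.cy) / intr.f
    pts[..., 2] = depth
    return pts


def backproject_roi(depth: np.ndarray, roi: np.ndarray,
                    intr: CameraIntrinsics) -> np.ndarray:
    """Back-project the pixels of an ROI, keeping grid alignment.

    Returns an ``(H, W, 3)`` array whose entries are 3D points inside the ROI
    and NaN outside, so that pixel adjacency (needed for triangulation) is
    preserved.

    Raises
    ------
    InvalidDepthError
        If any ROI pixel is unmeasured (depth 0); depth correction must run
        first.  The error names the offending pixel.
    """
    depth = np.asarray(depth, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != depth.shape:
        raise DimensionMismatchError(
            f"roi shape {roi.shape} does not match depth {depth.shape}")
    bad = roi & (depth <= 0)
    if bad.any():
        y, x = np.argwhere(bad)[0]
        raise InvalidDepthError(
            f"unmeasured depth inside ROI at pixel (x={x}, y={y}); "
            "run depth correction before back-projecting")
    pts = backproject_grid(depth, intr)
    pts[~roi] = np.nan
    return pts
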