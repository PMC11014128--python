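"""Image and config I/O.

Depth images are 16-bit single-channel PNGs whose pixel value is depth in
millimeters (0 = unmeasured).  Label masks are 8-bit PNGs with a JSON sidecar
mapping region id to food name.  Depth stacks are directories of numbered
16-bit PNGs.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_depth_png", "write_depth_png",
    "read_label_png", "write_label_png",
    "read_color_png", "write_color_png",
    "read_depth_stack", "write_depth_stack",
]


def read_depth_png(path: str | Path) -> np.ndarray:
    """Read a 16-bit depth PNG into a float array of mm values."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: depth PNG must be single-channel, got shape {arr.shape}")
    return arr.astype(float)


def write_depth_png(path: str | Path, depth: np.ndarray) -> None:
    """Write depth (mm) as 16-bit PNG; values are rounded and clipped to [0, 65535]."""
    arr = np.clip(np.rint(np.asarray(depth)), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def read_label_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # tolerate palettized/expanded grayscale
        arr = arr[..., 0]
    return arr.astype(np.int32)


def write_label_png(path: str | Path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("label ids must fit in 8 bits")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_color_png(path: str | Path) -> np.ndarray:
    return iio.imread(path)


def write_color_png(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(Path(path), np.clip(np.rint(img), 0, 255).astype(np.uint8))


def read_depth_stack(path: str | Path) -> np.ndarray:
    """Read a depth stack from a directory of 16-bit PNGs (sorted by name) or
    a single PNG (stack of one frame).  Returns an (N, H, W) float array."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        return np.stack([read_depth_png(p) for p in files])
    return read_depth_png(path)[None]


def write_depth_stack(dirpath: str | Path, stack: np.ndarray) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack):
        write_depth_png(dirpath / f"frame_{i:04d}.png", frame)
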