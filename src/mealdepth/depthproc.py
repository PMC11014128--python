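"""Depth-image correction and post-warp compensation.

Consumer depth sensors produce two characteristic artifacts: temporal jitter
(a pixel's value flickers within a few mm of the true distance across
consecutive frames, with the true value the most frequent) and unmeasured
pixels near depth discontinuities (value 0).  Both are corrected at capture
level: the per-pixel mode over a stack of consecutive frames removes the
jitter, and a 7x7 mean filter over measured neighbors fills the holes.

After the post-meal depth image is warped into the pre-meal frame, a pixel's
value still encodes distance measured at its *source* location, so an object
can appear to sit below the table at its new location.  Since the camera and
table are fixed, the height above the table is invariant; the compensation

    d~(x~, y~) = d(x, y) - (b(x, y) - b(x~, y~))

(with b the empty-table background depth and (x, y) the warp source of
(x~, y~)) restores consistency with the background at the warped location.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .errors import InvalidDepthError

logger = logging.getLogger(__name__)

__all__ = ["temporal_mode", "fill_unmeasured", "compensate_warped_depth", "correct_capture"]


def temporal_mode(stack: np.ndarray) -> np.ndarray:
    """Per-pixel mode over a stack of consecutive depth frames.

    Zeros (unmeasured) never vote: a pixel is 0 in the output only if it is
    unmeasured in every frame.  Ties are broken toward the smallest value.

    Parameters
    ----------
    stack : (N, H, W) array
        N >= 1 depth frames in mm.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty (N, H, W) array")
    s = np.sort(stack, axis=0)  # ascending: zeros first, ties adjacent
    # run-length scan along the frame axis; a strictly-greater test keeps the
    # earlier (smaller) value on ties, and zero runs are never counted
    cur_val = s[0].astype(float)
    cur_cnt = (cur_val != 0).astype(np.int64)
    best_val = cur_val.copy()
    best_cnt = cur_cnt.copy()
    for i in range(1, s.shape[0]):
        frame = s[i].astype(float)
        cont = frame == cur_val
        cur_cnt = np.where(cont, cur_cnt + 1, 1)
        cur_val = frame
        cur_cnt = np.where(cur_val == 0, 0, cur_cnt)   # zero runs never count
        win = cur_cnt > best_cnt
        best_val = np.where(win, cur_val, best_val)
        best_cnt = np.where(win, cur_cnt, best_cnt)
    best_val[best_cnt == 0] = 0
    return best_val


def fill_unmeasured(depth: np.ndarray, *, window: int = 7) -> np.ndarray:
    """Fill unmeasured (0) pixels with the local mean of measured neighbors.

    Each 0-valued pixel is replaced by the mean of the nonzero pixels in its
    ``window`` x ``window`` neighborhood, computed from the pass's input (not
    progressively within a pass); passes repeat until no zeros remain or a
    pass changes nothing (hole wider than the window everywhere).  Measured
    pixels are never modified.

    Raises
    ------
    InvalidDepthError
        If the image contains no measured pixel at all.
    """
    depth = np.asarray(depth, dtype=float)
    if not (depth != 0).any():
        raise InvalidDepthError("cannot fill an all-zero depth image")
    out = depth.copy()
    while True:
        holes = out == 0
        if not holes.any():
            break
        valid = (~holes).astype(float)
        sums = ndimage.uniform_filter(out, size=window, mode="constant") * window ** 2
        cnts = np.rint(ndimage.uniform_filter(valid, size=window, mode="constant")
                       * window ** 2)
        fillable = holes & (cnts > 0)
        if not fillable.any():
            break
        out[fillable] = sums[fillable] / cnts[fillable]
    return out


def compensate_warped_depth(warped_depth: np.ndarray,
                            background: np.ndarray,
                            H: np.ndarray) -> tuple[np.ndarray, int]:
    """Background-referenced compensation of a warped depth image.

    For each warped pixel (x~, y~) with source (x, y) = H^{-1}(x~, y~)
    (nearest-neighbor, matching the depth warp's lookup):

        d~(x~, y~) = d(x, y) - (b(x, y) - b(x~, y~))

    where b is the corrected empty-table background (no zeros).  Unmeasured
    warped pixels (0) pass through as 0.  Negative results are clamped to 0;
    the clamp count is returned and logged.

    Returns
    -------
    (compensated, n_clamped)
    """
    from .alignment import inverse_map  # local import to avoid cycle

    warped = np.asarray(warped_depth, dtype=float)
    bg = np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise InvalidDepthError("background must be corrected (strictly positive)")
    if warped.shape != bg.shape:
        raise InvalidDepthError(
            f"warped depth {warped.shape} and background {bg.shape} shapes differ")
    src_x, src_y = inverse_map(H, warped.shape)
    ix = np.rint(src_x).astype(int)
    iy = np.rint(src_y).astype(int)
    h, w = bg.shape
    inside = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    out = np.zeros_like(warped)
    measured = (warped > 0) & inside
    b_src = bg[iy[measured], ix[measured]]
    out[measured] = warped[measured] - (b_src - bg[measured])
    negative = out < 0
    n_clamped = int(np.count_nonzero(negative))
    if n_clamped:
        logger.warning("compensation clamped %d negative depth pixels to 0", n_clamped)
        out[negative] = 0.0
    return out, n_clamped


def correct_capture(stack: np.ndarray) -> np.ndarray:
    """Capture-level correction: temporal mode, then hole filling."""
    return fill_unmeasured(temporal_mode(stack))
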