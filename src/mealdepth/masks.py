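"""Per-food region masks, ROI definition, and region-overlap (IoU) evaluation.

Segmentation itself is an external input: any detector can plug in by writing
an 8-bit label PNG (0 = background, k > 0 = region id) with a JSON sidecar
``{"1": "kimchi", ...}``.  The pre-meal food regions define the ROIs used on
both depth images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import imio
from .errors import DimensionMismatchError

__all__ = ["RegionMask", "load_masks", "save_masks", "compute_iou", "rois_from_premeal"]


@dataclass
class RegionMask:
    """A label grid (0 = background, k > 0 = region id) plus id->name map."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(k) for k in ids if k > 0]

    def region(self, region_id: int) -> np.ndarray:
        """Boolean mask of one region."""
        return self.labels == region_id

    def name_of(self, region_id: int) -> str:
        return self.names.get(region_id, f"region_{region_id}")


def load_masks(path: str | Path, expected_shape: tuple[int, int] | None = None) -> RegionMask:
    """Load a label PNG and its JSON sidecar (``<stem>.json`` next to it)."""
    path = Path(path)
    labels = imio.read_label_png(path)
    if expected_shape is not None and labels.shape != tuple(expected_shape):
        raise DimensionMismatchError(
            f"{path}: mask shape {labels.shape} does not match expected {tuple(expected_shape)}")
    sidecar = path.with_suffix(".json")
    names: dict[int, str] = {}
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return RegionMask(labels, names)


def save_masks(mask: RegionMask, path: str | Path) -> None:
    """Write label PNG + JSON sidecar; round-trips losslessly for ids <= 255."""
    path = Path(path)
    imio.write_label_png(path, mask.labels)
    path.with_suffix(".json").write_text(
        json.dumps({str(k): v for k, v in mask.names.items()}, indent=2))


def compute_iou(g: np.ndarray, d: np.ndarray) -> float:
    """Intersection-over-union of two pixel regions, |G∩D| / |G∪D|.

    Both regions empty is defined as perfect (vacuous) agreement, 1.0.
    """
    g = np.asarray(g, dtype=bool)
    d = np.asarray(d, dtype=bool)
    if g.shape != d.shape:
        raise DimensionMismatchError(f"shapes differ: {g.shape} vs {d.shape}")
    union = np.count_nonzero(g | d)
    if union == 0:
        return 1.0
    return np.count_nonzero(g & d) / union


def rois_from_premeal(pre_masks: RegionMask) -> dict[int, np.ndarray]:
    """ROIs for intake estimation: one boolean mask per pre-meal food region.

    The identical ROI set is applied to both the pre- and post-meal depth
    images, so that the differenced space volumes refer to the same frustum.
    """
    return {k: pre_masks.region(k) for k in pre_masks.region_ids}
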