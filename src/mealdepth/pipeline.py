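"""End-to-end intake estimation: capture correction -> plate alignment ->
depth compensation -> ROI definition -> space volumes -> per-food intake.

Two entry points: :func:`estimate_meal` runs on in-memory arrays (the API
tests and batch callers use), and :func:`run_pipeline` reads a YAML/JSON
config naming the input files and produces a machine-readable report.
Each stage's failures surface as :class:`PipelineError` carrying the stage
name and, for file-driven runs, a partial report of the stages that
completed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import imio
from .alignment import align_post_meal
from .camera import CameraIntrinsics
from .depthproc import compensate_warped_depth, correct_capture
from .errors import MealDepthError, PipelineError
from .masks import RegionMask, compute_iou, load_masks, rois_from_premeal
from .volume import estimate_intake

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = ["IntakeReport", "estimate_meal", "run_pipeline", "SCHEMA_VERSION"]


@dataclass
class IntakeReport:
    """Structured result of a pipeline run."""

    foods: list[dict]
    homography: list[list[float]]
    alignment_iou: float
    n_clamped: int
    flags: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        """JSON-ready report; volumes in cm^3 rounded to 2 decimals, with the
        reported intake equal to the difference of the reported volumes."""
        foods = []
        for f in self.foods:
            pre = round(f["pre_cm3"], 2)
            post = round(f["post_cm3"], 2)
            foods.append({**f, "pre_cm3": pre, "post_cm3": post,
                          "intake_cm3": round(post - pre, 2)})
        return {
            "schema_version": self.schema_version,
            "foods": foods,
            "homography": self.homography,
            "alignment_iou": round(self.alignment_iou, 4),
            "clamped_pixels": self.n_clamped,
            "flags": self.flags,
            "config": self.config,
        }


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False
    return _Ctx()


def estimate_meal(pre_stack: np.ndarray,
                  post_stack: np.ndarray,
                  background_stack: np.ndarray,
                  pre_plate_mask: np.ndarray,
                  post_plate_mask: np.ndarray,
                  pre_food_masks: RegionMask,
                  intr: CameraIntrinsics,
                  post_food_masks: RegionMask | None = None,
                  config_echo: dict | None = None) -> IntakeReport:
    """Full intake estimation on in-memory depth stacks and masks.

    Stacks are (N, H, W); N = 1 skips nothing (the temporal mode of a single
    frame is the frame itself, which is logged).  The post-meal capture is
    aligned onto the pre-meal plate, compensated against the background, and
    differenced over the pre-meal food ROIs.
    """
    with _stage("capture-correction"):
        for name, stack in (("pre", pre_stack), ("post", post_stack),
                            ("background", background_stack)):
            if np.asarray(stack).shape[0] == 1:
                logger.info("%s capture is a single frame; temporal mode is a no-op", name)
        pre_depth = correct_capture(np.asarray(pre_stack))
        post_depth = correct_capture(np.asarray(post_stack))
        background = correct_capture(np.asarray(background_stack))

    with _stage("alignment"):
        aligned = align_post_meal(pre_plate_mask, post_plate_mask,
                                  post_depth=post_depth,
                                  post_food_masks=post_food_masks)
        iou = compute_iou(np.asarray(pre_plate_mask) != 0, aligned.plate_mask)

    with _stage("compensation"):
        compensated, n_clamped = compensate_warped_depth(
            aligned.depth, background, aligned.H)
        holes = compensated == 0
        if holes.any():
            # warp border / dropout holes: fill so ROIs stay integrable
            from .depthproc import fill_unmeasured
            compensated = fill_unmeasured(compensated)

    with _stage("roi"):
        rois = rois_from_premeal(pre_food_masks)
        if not rois:
            raise MealDepthError("pre-meal mask defines no food regions")

    with _stage("volume"):
        estimates = estimate_intake(pre_depth, compensated, rois, intr,
                                    names=pre_food_masks.names)

    flags = []
    foods = []
    for e in estimates:
        if e.negative:
            flags.append(f"negative intake for {e.name}")
        foods.append({
            "region_id": e.region_id, "name": e.name,
            "pre_cm3": e.pre_cm3, "post_cm3": e.post_cm3,
            "intake_cm3": e.intake_cm3, "negative": e.negative,
        })
    if n_clamped:
        flags.append(f"{n_clamped} compensated pixels clamped to 0")
    return IntakeReport(foods=foods, homography=aligned.H.tolist(),
                        alignment_iou=iou, n_clamped=n_clamped, flags=flags,
                        config=config_echo or {})


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def run_pipeline(config: dict | str | Path) -> IntakeReport:
    """Run the pipeline from a config naming input files.

    Config keys::

        intrinsics: path (yaml/json) or inline {f, cx, cy, width, height}
        background_depth: 16-bit PNG or directory of frames
        pre:  {depth: path, plate_mask: path, food_masks: path}
        post: {depth: path, plate_mask: path, food_masks: path (optional)}

    Deterministic: identical inputs reproduce the report bit-identically.
    """
    cfg = _load_config(config)
    with _stage("config"):
        for key in ("intrinsics", "background_depth", "pre", "post"):
            if key not in cfg:
                raise MealDepthError(f"config missing required key '{key}'")
        intr_cfg = cfg["intrinsics"]
        intr = (CameraIntrinsics(**intr_cfg) if isinstance(intr_cfg, dict)
                else CameraIntrinsics.from_file(intr_cfg))
        paths = {
            "background": Path(cfg["background_depth"]),
            "pre_depth": Path(cfg["pre"]["depth"]),
            "pre_plate": Path(cfg["pre"]["plate_mask"]),
            "pre_foods": Path(cfg["pre"]["food_masks"]),
            "post_depth": Path(cfg["post"]["depth"]),
            "post_plate": Path(cfg["post"]["plate_mask"]),
        }
        for name, p in paths.items():
            if not p.exists():
                raise MealDepthError(f"input file for '{name}' not found: {p}")

    with _stage("load"):
        pre_stack = imio.read_depth_stack(paths["pre_depth"])
        post_stack = imio.read_depth_stack(paths["post_depth"])
        bg_stack = imio.read_depth_stack(paths["background"])
        pre_plate = imio.read_label_png(paths["pre_plate"]) != 0
        post_plate = imio.read_label_png(paths["post_plate"]) != 0
        pre_foods = load_masks(paths["pre_foods"], expected_shape=intr.shape)
        post_foods = None
        if cfg["post"].get("food_masks"):
            post_foods = load_masks(Path(cfg["post"]["food_masks"]),
                                    expected_shape=intr.shape)

    return estimate_meal(pre_stack, post_stack, bg_stack, pre_plate,
                         post_plate, pre_foods, intr,
                         post_food_masks=post_foods, config_echo=cfg)


def write_report(report: IntakeReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
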