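# mealdepth

Estimates how much of each food was eaten from two RGB-D captures of a meal
plate — one before and one after eating — using a fixed top-down depth
camera. No knowledge of food or container shape is required: the method
measures the *space volume* between the camera and the visible surface over
each food region and reports intake as the growth of that volume after the
meal.

It is aimed at dietary-assessment research: automated intake measurement at
a meal table with a consumer depth camera (e.g. a RealSense-class sensor),
with per-food segmentation masks supplied by any external detector.

## Method

For a pinhole camera with focal length `f` (pixels) and optical center
`(cx, cy)`, a pixel `(x, y)` with measured depth `d` mm back-projects to

    X = d (x − cx) / f,   Y = d (y − cy) / f,   Z = d.

The pixels of a food ROI (its pre-meal segmentation region) are split into
unit triangles; each triangle's three back-projected points form the base of
a tetrahedron with apex at the camera origin and volume `V = s·h/3` (base
area `s`, base-plane distance to the origin `h`). Summing tetrahedra gives
the camera-to-surface space volume over the ROI, and

    intake_i = space_volume(post, ROI_i) − space_volume(pre, ROI_i),

since eating lowers the food surface, moving it farther from the camera.
Volume hidden behind container walls is identical in both captures and
cancels in the difference.

Before differencing, the captures are registered and corrected:

* **Plate alignment** — the meal plate's four corners are found per capture
  as the minimum-area enclosing rectangle of the plate mask (rotating
  calipers over its convex hull); the exact 4-point homography `H`
  (an 8×8 linear solve, `h = a⁻¹b`) warps the post-meal color, depth, and
  masks onto the pre-meal frame. Depth warps nearest-neighbor — bilinear
  interpolation across a depth edge would fabricate surfaces.
* **Depth compensation** — a warped depth value still encodes distance at
  its source pixel, so it is corrected against the empty-table background
  `b`: `d̃(x̃,ỹ) = d(x,y) − (b(x,y) − b(x̃,ỹ))`, preserving height above
  the table.
* **Sensor-noise correction** — per-pixel mode over 30 consecutive frames
  (zeros excluded, ties to the smaller value) removes temporal jitter; a
  7×7 mean filter over measured neighbors fills unmeasured (zero) pixels.

A perspective ray-casting scene generator (`mealdepth.synth`) renders
parametric solids of exactly known volume — cuboids, cylinders, bowls with a
liquid fill, bilinear height maps — on a movable plate, with seeded jitter
and edge-dropout noise, so the whole pipeline is testable against analytic
ground truth.

## Worked example

Render a 200 cm³ water bowl on a plate, drink half, nudge and rotate the
plate, and estimate the intake from the noisy captures:

```python
import numpy as np
import mealdepth as md

intr = md.CameraIntrinsics(f=598.05, cx=319.48, cy=241.50, width=640, height=480)
fill = 200_000 / (np.pi * 55**2)                  # 200 cm^3 in a 55 mm bowl
bowl = md.BowlWithFill(0, 0, inner_radius=55, outer_radius=60, height=55,
                       base_thickness=6, fill_height=fill, region_id=1)
spec = md.SceneSpec(plate=md.Plate(), solids=[bowl])

pair = md.make_meal_pair(spec, {1: 0.5}, intr, translate_px=(20, 0),
                         rotate_deg=5.0, noise=md.NoiseModel(), n_frames=30,
                         rng=np.random.default_rng(123))
report = md.estimate_meal(pair.pre_stack, pair.post_stack, pair.background_stack,
                          pair.pre.plate_mask, pair.post.plate_mask,
                          pair.pre.food_mask, intr)
food = report.foods[0]
print(f"intake {food['intake_cm3']:.2f} cm^3, truth {pair.gt_intake_cm3[1]:.1f}")
print(f"alignment IoU {report.alignment_iou:.4f}")
```

prints

```
intake 99.10 cm^3, truth 100.0
alignment IoU 0.9948
```

i.e. a 0.9 % intake error despite the plate having moved 20 px and rotated
5° between captures, with ±1 mm temporal jitter and 1 % edge dropout on
every frame. The same run is available from the shell via the
`intake-pipeline` CLI (`synth`, `align`, `volume`, `intake`, and `run`
subcommands; `run` takes a YAML config naming the depth stacks, masks,
background, and intrinsics and writes a JSON report).

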