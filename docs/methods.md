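# Methods

## Measurement model

The quantity actually measured is a *frustum volume*: for an ROI `R` and a
depth image `d`, the space volume is the volume of the 3D region bounded by
the camera origin and the back-projected surface over `R`'s view frustum.
It is computed exactly for a piecewise-linear surface by splitting every
unit pixel square whose four pixels lie in `R` along its top-left →
bottom-right diagonal and summing tetrahedron volumes `s·h/3` (base area
from the edge cross product, base-plane distance from the determinant form
of the plane through the three vertices; algebraically identical to the
scalar triple product `|v1·(v2×v3)|/6`, which the tests use as an
independent oracle). For a constant-depth plane `Z` over an `a×b`-pixel
rectangle this sum telescopes to `(a−1)(b−1)·Z³/(3f²)`, the closed form
used as a second oracle.

Intake is the signed difference of post- and pre-meal space volumes over
the *pre-meal* food regions. Differencing is what makes the method
container-free: the region between the two surfaces along the ROI rays is
exactly the material that disappeared, and volume occluded by container
walls is common to both captures and cancels. Negative intakes are
reported, flagged, and never clamped — they are the caller's signal that
alignment or noise dominated a small region.

Two geometric facts worth knowing when interpreting outputs:

* **Single-capture background subtraction measures a frustum slab, not a
  solid volume.** Differencing one object against the empty table over its
  silhouette ROI yields the slab between its top surface and the table
  *within the diverging frustum* — for a flat-topped prism of height `h`
  with top at `Zt`, `A·(D³−Zt³)/(3·Zt²)` rather than `A·h` (table at `D`).
  The surplus is the perspective wedge along the side walls; it grows with
  object height (≈25 % for a 75 mm prism at 400 mm, ≈2.6 % at 10 mm). The
  package exposes this interpretation as-is; pre/post differencing of the
  same scene cancels the wedge, which is why intake errors are far smaller
  than this bias.
* **A plane homography cannot align points off the plate plane.** After
  alignment, a surface at height `h` above the plate is still misregistered
  by roughly `shift_px · h / table_depth` pixels of parallax (rotation about
  the optical axis is exempt). The residual intake error this causes scales
  with the surface-height discontinuity at the ROI boundary: it is near
  zero for foods that taper to the plate (piles, mounds) or for recessed
  liquid surfaces, and worst for tall vertical-walled blocks. This is a
  limitation of the alignment model itself, not of the implementation.

## Pipeline stages and conventions

Order: temporal mode → hole filling (both per capture, before alignment) →
corner detection → homography → warp → background compensation → ROI
definition → volumes → intake.

* Pixels are 0-based, `(x=column, y=row)`, centers at integer coordinates;
  depths in mm (16-bit PNG, 0 = unmeasured); volumes reported in cm³.
* Plate corners: minimum-area enclosing rectangle of the plate mask's
  convex hull (shapely's rotating-calipers implementation); vertices
  ordered clockwise (image coordinates, y down) starting nearest the image
  origin. Corner correspondence across captures relies on that shared
  ordering and therefore assumes plate rotation < 45° between captures — a
  reasonable meal scenario; manual corner override is available.
* The homography is the exact 4-point solve of the 8×8 system via a general
  linear solver (numerically equivalent to inverting the matrix, better
  conditioned). Degenerate (collinear) configurations raise.
* Depth and label images warp nearest-neighbor on the inverse map; color
  warps bilinearly. Compensation reuses the *same* nearest-neighbor inverse
  lookup as the depth warp, which makes height above the background exactly
  invariant (≤ 1 mm, the depth quantum) — the property the compensation
  exists to provide.
* Temporal mode: zeros (unmeasured) never vote; a pixel stays 0 only if
  unmeasured in every frame; ties break to the smaller value (a fixed,
  conservative rule — sensors overestimate range more often at edges).
* Hole filling: each zero pixel takes the mean of measured pixels in its
  7×7 window, recomputed per pass from the previous pass's result until no
  zeros remain or nothing changes; measured pixels are never altered.
  Single-pass filling handles holes up to ~5 px wide; wider holes converge
  over passes.
* Compensated depths below zero are clamped to 0 and counted; the count is
  logged and reported (`clamped_pixels`).
* Triangles must have all three vertices inside the ROI, so no tetrahedron
  borrows depth from a neighboring object across a mask boundary. The
  diagonal split direction is fixed for determinism; any consistent choice
  differs by sub-pixel terms.
* Report volumes are rounded to 2 decimals with the reported intake equal
  to the difference of the reported volumes.

## Synthetic scenes

The generator emulates the reference capture geometry: 640×480, `f =
598.05`, optical center `(319.48, 241.50)`, camera 400 mm above the table,
looking straight down. Scenes are rendered by perspective ray casting —
each pixel's depth is the Z of the first surface hit along its ray — so
tall solids project wider than their bases exactly as the volume engine
assumes; an orthographic height-map stamp would hide the perspective
effects discussed above. Solids: cuboids and vertical prisms (rotatable
footprint), cylinders, bowls (vertical-walled annulus with a flat liquid
surface; the liquid is the food), and bilinear height-map solids for
irregular piles (ray-marched at 0.5 mm with secant refinement; ground truth
is the exact bilinear integral). The plate is a thin rectangular prism
(280×220×10 mm by default); the rendered plate mask contains the pixels
whose *visible* surface is the plate, matching what an image segmenter
would label — foods punch holes in it, which corner finding tolerates via
the convex hull as long as the corners stay visible (scenes must not let a
tall solid overhang a plate corner).

Noise model, matching the two artifacts the correction stage targets:
per-frame temporal jitter peaked at the true value (the pixel deviates with
probability 0.3, uniformly ±1 mm by default — a peaked distribution is what
makes a mode filter the right estimator, and is how the underlying sensor
behaves), and edge dropout (zeros within 2 px of a >5 mm depth
discontinuity, 1 % probability) with both a transient per-frame component
and a persistent component fixed across the stack so that spatial hole
filling has real work after the temporal mode.

What the generator does **not** emulate: range-dependent noise magnitude,
material/reflectance effects, multi-path distortion, lens distortion,
rolling capture, or imperfect segmentation masks (masks are rendered
ground truth). Passing tests therefore demonstrate the geometric pipeline's
correctness and its robustness to jitter/dropout at realistic levels — not
robustness to detector errors or to sensor physics beyond this model.

## Benchmark scenarios and problem sizes

The acceptance script and end-to-end tests run full-resolution (640×480)
pairs with 30-frame stacks:

* *Water bowl*: 200 cm³ in a 55 mm-radius bowl, 100 cm³ removed; plate
  translated 20 px and rotated 5°. The bowl (55 mm tall, vertical walls) is
  the container; the ROI is the water surface, recessed below the rim.
* *Low-profile solid*: a 100×75×12 mm block (90 cm³) reduced to 8 mm
  (60 cm³); plate translated 15 px.
* *Registration cancellation*: a tapered paraboloid mound (≈98 cm³) and a
  shallow soup bowl (150 cm³, liquid near the rim) off plate center, zero
  intake, plate translated (20, 5) px and rotated 5°. Tapered and recessed
  surfaces are the realistic regime for this property (see the parallax
  note above); the spurious intake stays below 0.5 % of each food's volume.

Unit tests use a reduced 160×120 geometry where full resolution adds
nothing.

## Known limitations

* Parallax residual for tall, sharp-edged foods scales with plate movement;
  the method degrades gracefully (the water-bowl scenario stays under 1 %
  at 20 px + 5°) but a block-shaped 30 mm food with a 15 px shift can reach
  several percent.
* The ROI comes from the pre-meal segmentation only; food pushed *outside*
  its pre-meal region (rearranged rather than eaten) is measured as intake.
* Single focal length (square pixels), no lens distortion, no extrinsics:
  the camera must be fixed between all three captures (background, pre,
  post).
* Bowls are modeled with vertical walls; real tapered bowls only make the
  cancellation properties easier.
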