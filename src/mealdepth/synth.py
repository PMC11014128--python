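"""Synthetic RGB-D scene renderer with analytic ground truth.

Emulates a top-down depth camera about 40 cm above a table: parametric
solids (cuboids, cylinders, bowls with a liquid fill, height maps) sit on a
table plane or on a rectangular plate, and each pixel's depth is the Z of
the first surface met by the perspective ray through that pixel.  Solids
occupy their true 3D footprint — a tall object near the image edge projects
wider than its base, exactly as the volume engine's frustum integration
assumes — so an orthographic stamp would hide systematic errors that this
renderer exposes.

Every solid has a closed-form volume, so rendered scenes carry exact ground
truth for the estimation pipeline.  A seeded noise model reproduces the two
sensor artifacts the correction stage targets: temporal jitter peaked at the
true value, and unmeasured pixels (zeros) near depth discontinuities, with a
persistent component that survives the temporal mode.

Scene coordinates: the camera sits at the origin looking down +Z; X, Y are
mm in the camera frame (X right, Y down in the image).  A solid placed at
(0, 0) is on the optical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .camera import CameraIntrinsics
from .masks import RegionMask

__all__ = [
    "Cuboid", "Cylinder", "BowlWithFill", "HeightMapSolid", "Plate",
    "SceneSpec", "NoiseModel", "RenderedScene", "MealPair",
    "render_scene", "apply_noise", "make_meal_pair", "load_scene_spec",
]

_INF = np.inf


def _slab_interval(p: np.ndarray, q: np.ndarray, half: float):
    """Z-interval where |p*Z - q| <= half, per pixel (lo, hi; empty -> lo > hi)."""
    lo = np.full_like(p, -_INF)
    hi = np.full_like(p, _INF)
    nz = np.abs(p) > 1e-15
    a = (q - half) / np.where(nz, p, 1.0)
    b = (q + half) / np.where(nz, p, 1.0)
    lo = np.where(nz, np.minimum(a, b), lo)
    hi = np.where(nz, np.maximum(a, b), hi)
    outside = ~nz & (np.abs(q) > half)
    lo = np.where(outside, _INF, lo)
    hi = np.where(outside, -_INF, hi)
    return lo, hi


def _cylinder_interval(kx: np.ndarray, ky: np.ndarray, x0: float, y0: float, r: float):
    """Z-interval where the ray (kx*Z, ky*Z) lies within radius r of (x0, y0)."""
    a = kx ** 2 + ky ** 2
    b = -2.0 * (kx * x0 + ky * y0)
    c = x0 ** 2 + y0 ** 2 - r ** 2
    lo = np.full_like(kx, _INF)
    hi = np.full_like(kx, -_INF)
    lin = a <= 1e-18
    inside_always = lin & (c <= 0)
    lo = np.where(inside_always, -_INF, lo)
    hi = np.where(inside_always, _INF, hi)
    disc = b ** 2 - 4 * a * c
    ok = ~lin & (disc >= 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    a_safe = np.where(ok, a, 1.0)
    t1 = (-b - sq) / (2 * a_safe)
    t2 = (-b + sq) / (2 * a_safe)
    lo = np.where(ok, t1, lo)
    hi = np.where(ok, t2, hi)
    return lo, hi


@dataclass(frozen=True)
class Cuboid:
    """Axis-vertical rectangular box standing on its support surface."""

    x: float                 # center X, mm
    y: float                 # center Y, mm
    length: float            # extent along local X, mm
    width: float             # extent along local Y, mm
    height: float            # mm above the support
    angle_deg: float = 0.0   # rotation of the footprint about its center
    region_id: int = 1
    on_plate: bool = True

    @property
    def volume_cm3(self) -> float:
        return self.length * self.width * self.height / 1000.0

    def footprint_radius(self) -> float:
        return 0.5 * float(np.hypot(self.length, self.width))

    def hit(self, kx, ky, z_support):
        z_top = z_support - self.height
        th = np.deg2rad(self.angle_deg)
        ct, st = np.cos(th), np.sin(th)
        pu = ct * kx + st * ky
        qu = ct * self.x + st * self.y
        pv = -st * kx + ct * ky
        qv = -st * self.x + ct * self.y
        lo_u, hi_u = _slab_interval(pu, qu, self.length / 2)
        lo_v, hi_v = _slab_interval(pv, qv, self.width / 2)
        lo = np.maximum(np.maximum(lo_u, lo_v), z_top)
        hi = np.minimum(np.minimum(hi_u, hi_v), z_support)
        z = np.where(lo <= hi, lo, _INF)
        labels = np.where(np.isfinite(z), self.region_id, 0)
        return z, labels

    def reduced(self, fraction: float) -> "Cuboid":
        return replace(self, height=self.height * (1 - fraction))


@dataclass(frozen=True)
class Cylinder:
    """Vertical circular cylinder standing on its support surface."""

    x: float
    y: float
    radius: float
    height: float
    region_id: int = 1
    on_plate: bool = True

    @property
    def volume_cm3(self) -> float:
        return np.pi * self.radius ** 2 * self.height / 1000.0

    def footprint_radius(self) -> float:
        return self.radius

    def hit(self, kx, ky, z_support):
        z_top = z_support - self.height
        lo_c, hi_c = _cylinder_interval(kx, ky, self.x, self.y, self.radius)
        lo = np.maximum(lo_c, z_top)
        hi = np.minimum(hi_c, z_support)
        z = np.where(lo <= hi, lo, _INF)
        labels = np.where(np.isfinite(z), self.region_id, 0)
        return z, labels

    def reduced(self, fraction: float) -> "Cylinder":
        return replace(self, height=self.height * (1 - fraction))


@dataclass(frozen=True)
class BowlWithFill:
    """Cylindrical bowl (opaque walls) holding a liquid with a flat surface.

    The *food* is the liquid: its ground-truth volume is
    ``pi * inner_radius^2 * fill_height``.  The bowl wall and base occlude
    rays but carry ``wall_id`` (0 = unlabeled) in the mask.  ``fill_height``
    is measured from the inner cavity bottom.
    """

    x: float
    y: float
    inner_radius: float
    outer_radius: float
    height: float            # rim height above the support, mm
    base_thickness: float    # cavity bottom sits this far above the support
    fill_height: float       # liquid depth, mm
    region_id: int = 1
    wall_id: int = 0
    on_plate: bool = True

    def __post_init__(self):
        if self.inner_radius >= self.outer_radius:
            raise ValueError("inner radius must be smaller than outer radius")
        if self.fill_height > self.height - self.base_thickness:
            raise ValueError("fill exceeds cavity depth")

    @property
    def volume_cm3(self) -> float:
        return np.pi * self.inner_radius ** 2 * self.fill_height / 1000.0

    def footprint_radius(self) -> float:
        return self.outer_radius

    def hit(self, kx, ky, z_support):
        z_rim = z_support - self.height
        z_cav_bot = z_support - self.base_thickness
        z_water = z_cav_bot - self.fill_height
        lo_o, hi_o = _cylinder_interval(kx, ky, self.x, self.y, self.outer_radius)
        lo_i, hi_i = _cylinder_interval(kx, ky, self.x, self.y, self.inner_radius)
        lo = np.maximum(lo_o, z_rim)
        hi = np.minimum(hi_o, z_support)
        hit_any = lo <= hi
        z0 = np.where(hit_any, lo, _INF)
        # in the cavity at entry: strictly inside the inner cylinder and above
        # the cavity bottom -> the ray continues to inner wall, water, or base
        in_cavity = hit_any & (z0 > lo_i) & (z0 < hi_i) & (z0 < z_cav_bot)
        floor = z_water if self.fill_height > 0 else z_cav_bot
        z_cavity_hit = np.minimum(hi_i, floor)
        z = np.where(in_cavity, z_cavity_hit, z0)
        is_water = in_cavity & (self.fill_height > 0) & (floor <= hi_i)
        labels = np.where(np.isfinite(z),
                          np.where(is_water, self.region_id, self.wall_id), 0)
        return z, labels

    def reduced(self, fraction: float) -> "BowlWithFill":
        return replace(self, fill_height=self.fill_height * (1 - fraction))


@dataclass(frozen=True)
class HeightMapSolid:
    """Irregular solid given as a height grid over a rectangular footprint.

    ``heights`` is an (ny, nx) array of mm elevations above the support at
    the *corners* of an (ny-1) x (nx-1) cell grid with pitch ``spacing``; the
    surface is the bilinear interpolant, footprint centered at (x, y) and
    rotated by ``angle_deg``.  Outside the footprint the height is 0, so
    grids should taper to 0 at the boundary for a watertight shape (food
    piles do).  Ground-truth volume is the exact bilinear integral,
    ``spacing^2 * sum of per-cell corner means``.
    """

    x: float
    y: float
    spacing: float
    heights: tuple    # tuple-of-tuples for hashability; array accepted at init
    angle_deg: float = 0.0
    region_id: int = 1
    on_plate: bool = True

    def __post_init__(self):
        object.__setattr__(self, "heights",
                           tuple(tuple(float(v) for v in row) for row in self.heights))

    @property
    def _h(self) -> np.ndarray:
        return np.asarray(self.heights, dtype=float)

    @property
    def volume_cm3(self) -> float:
        h = self._h
        cell_mean = (h[:-1, :-1] + h[1:, :-1] + h[:-1, 1:] + h[1:, 1:]) / 4.0
        return float(cell_mean.sum()) * self.spacing ** 2 / 1000.0

    def footprint_radius(self) -> float:
        ny, nx = self._h.shape
        return 0.5 * self.spacing * float(np.hypot(nx - 1, ny - 1))

    def _surface(self, kx, ky, zc):
        """Bilinear surface depth under the ray point at depth zc (z_support units
        handled by caller); returns height above support (0 outside footprint)."""
        h = self._h
        ny, nx = h.shape
        hx, hy = (nx - 1) * self.spacing / 2, (ny - 1) * self.spacing / 2
        th = np.deg2rad(self.angle_deg)
        ct, st = np.cos(th), np.sin(th)
        X = kx * zc - self.x
        Y = ky * zc - self.y
        u = (ct * X + st * Y + hx) / self.spacing
        v = (-st * X + ct * Y + hy) / self.spacing
        iu = np.clip(np.floor(u).astype(int), 0, nx - 2)
        iv = np.clip(np.floor(v).astype(int), 0, ny - 2)
        inside = (u >= 0) & (u <= nx - 1) & (v >= 0) & (v <= ny - 1)
        fu = np.clip(u - iu, 0.0, 1.0)
        fv = np.clip(v - iv, 0.0, 1.0)
        hv = (h[iv, iu] * (1 - fu) * (1 - fv) + h[iv, iu + 1] * fu * (1 - fv)
              + h[iv + 1, iu] * (1 - fu) * fv + h[iv + 1, iu + 1] * fu * fv)
        return np.where(inside, hv, 0.0)

    def hit(self, kx, ky, z_support, step: float = 0.5):
        z_top = z_support - self._h.max()
        z = np.full_like(kx, _INF)
        undecided = np.ones(kx.shape, dtype=bool)
        n_steps = max(1, int(np.ceil((z_support - z_top) / step)))
        g_prev = np.full(kx.shape, -self._h.max())  # g(z) = z - surface_z; <0 above
        z_prev = np.full(kx.shape, z_top)
        for i in range(1, n_steps + 1):
            zc = min(z_top + i * step, z_support)
            g = zc - (z_support - self._surface(kx, ky, zc))
            crossed = undecided & (g >= 0)
            if crossed.any():
                denom = g[crossed] - g_prev[crossed]
                t = np.where(np.abs(denom) > 1e-12,
                             -g_prev[crossed] / np.where(np.abs(denom) > 1e-12, denom, 1.0),
                             1.0)
                z[crossed] = z_prev[crossed] + np.clip(t, 0.0, 1.0) * (zc - z_prev[crossed])
                undecided &= ~crossed
                if not undecided.any():
                    break
            g_prev, z_prev = g, np.full(kx.shape, zc)
        # a hit exactly on the support plane is the table/plate, not the solid
        z = np.where(z >= z_support - 1e-9, _INF, z)
        labels = np.where(np.isfinite(z), self.region_id, 0)
        return z, labels

    def reduced(self, fraction: float) -> "HeightMapSolid":
        h = self._h * (1 - fraction)
        return replace(self, heights=tuple(tuple(row) for row in h))


@dataclass(frozen=True)
class Plate:
    """Rectangular meal plate: a thin prism lying on the table."""

    x: float = 0.0
    y: float = 0.0
    length: float = 280.0
    width: float = 220.0
    height: float = 10.0
    angle_deg: float = 0.0

    def as_cuboid(self) -> Cuboid:
        return Cuboid(self.x, self.y, self.length, self.width, self.height,
                      self.angle_deg, region_id=0, on_plate=False)


@dataclass
class SceneSpec:
    """Parametric scene: table plane depth, optional plate, list of solids.

    Defaults place the table 400 mm below the camera (a 40 cm top-down
    capture).  Solids with ``on_plate=True`` stand on the plate's top face.
    """

    table_depth: float = 400.0
    plate: Plate | None = None
    solids: list = field(default_factory=list)

    def shifted(self, dx_mm: float, dy_mm: float, rot_deg: float) -> "SceneSpec":
        """Rigidly move plate + on-plate solids (rotation about plate center)."""
        if self.plate is None:
            raise ValueError("cannot shift a scene without a plate")
        p = self.plate
        th = np.deg2rad(rot_deg)
        ct, st = np.cos(th), np.sin(th)
        new_plate = replace(p, x=p.x + dx_mm, y=p.y + dy_mm,
                            angle_deg=p.angle_deg + rot_deg)
        new_solids = []
        for s in self.solids:
            if not s.on_plate:
                new_solids.append(s)
                continue
            rx, ry = s.x - p.x, s.y - p.y
            nx = ct * rx - st * ry + p.x + dx_mm
            ny = st * rx + ct * ry + p.y + dy_mm
            s = replace(s, x=nx, y=ny)
            if hasattr(s, "angle_deg"):
                s = replace(s, angle_deg=s.angle_deg + rot_deg)
            new_solids.append(s)
        return SceneSpec(self.table_depth, new_plate, new_solids)


_PALETTE = np.array([
    [200, 60, 60], [60, 160, 60], [70, 90, 200], [210, 160, 40],
    [150, 70, 170], [60, 180, 180], [230, 120, 160], [120, 120, 40],
], dtype=np.uint8)


@dataclass
class RenderedScene:
    """Noiseless render: depth (mm), food/plate masks, flat-shaded color, ground truth."""

    depth: np.ndarray
    food_mask: RegionMask
    plate_mask: np.ndarray
    color: np.ndarray
    volumes_cm3: dict[int, float]
    spec: SceneSpec


def render_scene(spec: SceneSpec, intr: CameraIntrinsics) -> RenderedScene:
    """Perspective ray-cast of a scene: first-hit depth, labels, ground truth.

    Raises ``ValueError`` if any solid's silhouette leaves the camera frustum.
    """
    ys, xs = np.mgrid[0:intr.height, 0:intr.width]
    kx = (xs - intr.cx) / intr.f
    ky = (ys - intr.cy) / intr.f

    depth = np.full(kx.shape, spec.table_depth)
    labels = np.zeros(kx.shape, dtype=np.int32)
    # plate mask = pixels whose *visible* surface is the plate (what an image
    # segmenter labels); occlusions by foods leave holes that the convex hull
    # in corner finding tolerates as long as the corners stay visible
    plate_hit = np.zeros(kx.shape, dtype=bool)

    plate_top = spec.table_depth
    renderables = []
    if spec.plate is not None:
        plate_top = spec.table_depth - spec.plate.height
        renderables.append((spec.plate.as_cuboid(), spec.table_depth, "plate"))
    for s in spec.solids:
        z_sup = plate_top if (s.on_plate and spec.plate is not None) else spec.table_depth
        renderables.append((s, z_sup, "solid"))

    for solid, z_sup, kind in renderables:
        _check_frustum(solid, z_sup, intr)
        z, lab = solid.hit(kx, ky, z_sup)
        closer = z < depth
        depth = np.where(closer, z, depth)
        labels = np.where(closer, lab, labels)
        if kind == "plate":
            plate_hit = closer.copy()
        else:
            plate_hit &= ~closer

    volumes = {s.region_id: s.volume_cm3 for s in spec.solids if s.region_id > 0}
    names = {rid: f"region_{rid}" for rid in volumes}
    color = np.full(kx.shape + (3,), 170, dtype=np.uint8)   # table
    color[plate_hit] = (235, 235, 235)
    wall = (labels == 0) & ~plate_hit & (depth < spec.table_depth - 1e-6)
    color[wall] = (120, 120, 120)
    for rid in volumes:
        color[labels == rid] = _PALETTE[(rid - 1) % len(_PALETTE)]
    return RenderedScene(depth=depth, food_mask=RegionMask(labels, names),
                         plate_mask=plate_hit, color=color,
                         volumes_cm3=volumes, spec=spec)


def _silhouette_points(solid) -> np.ndarray:
    """Extreme footprint points (mm, scene frame) bounding the solid's silhouette."""
    if isinstance(solid, (Cuboid, HeightMapSolid)):
        if isinstance(solid, Cuboid):
            hx, hy = solid.length / 2, solid.width / 2
        else:
            ny, nx = solid._h.shape
            hx, hy = (nx - 1) * solid.spacing / 2, (ny - 1) * solid.spacing / 2
        th = np.deg2rad(solid.angle_deg)
        ct, st = np.cos(th), np.sin(th)
        corners = np.array([[sx * hx, sy * hy] for sx in (-1, 1) for sy in (-1, 1)])
        rot = corners @ np.array([[ct, st], [-st, ct]])
        return rot + [solid.x, solid.y]
    r = solid.footprint_radius()
    return np.array([[solid.x + r, solid.y], [solid.x - r, solid.y],
                     [solid.x, solid.y + r], [solid.x, solid.y - r]])


def _check_frustum(solid, z_sup: float, intr: CameraIntrinsics) -> None:
    if isinstance(solid, HeightMapSolid):
        z_top = z_sup - solid._h.max()
    else:
        z_top = z_sup - solid.height
    z_top = max(z_top, 1.0)
    for X, Y in _silhouette_points(solid):
        px = intr.f * X / z_top + intr.cx
        py = intr.f * Y / z_top + intr.cy
        if not (0 <= px < intr.width and 0 <= py < intr.height):
            raise ValueError(
                f"solid at ({solid.x}, {solid.y}) leaves the camera frustum "
                f"(projected ({px:.0f}, {py:.0f}))")


@dataclass(frozen=True)
class NoiseModel:
    """Depth-sensor noise: value-peaked temporal jitter plus edge dropout.

    ``jitter_prob`` is the chance a pixel deviates from its true value in a
    frame (deviations uniform over +/-1..jitter_range mm); the true value
    stays the most frequent, which is what the temporal mode exploits.
    Dropout zeroes pixels within ``edge_width`` px of a depth discontinuity:
    a transient component independently per frame and a persistent component
    fixed across the stack (holes that survive the temporal mode and must be
    filled spatially), each with probability ``dropout_prob``.
    """

    jitter_range: int = 1
    jitter_prob: float = 0.3
    dropout_prob: float = 0.01
    edge_width: int = 2
    edge_threshold: float = 5.0
    seed: int | None = None


def apply_noise(depth: np.ndarray, nm: NoiseModel, n_frames: int = 30,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Jittered, dropout-afflicted stack of ``n_frames`` captures of a scene."""
    if rng is None:
        rng = np.random.default_rng(nm.seed)
    depth = np.asarray(depth, dtype=float)
    rng_local = (ndimage.maximum_filter(depth, 3) - ndimage.minimum_filter(depth, 3))
    edge = rng_local > nm.edge_threshold
    if nm.edge_width > 0:
        edge = ndimage.binary_dilation(edge, iterations=nm.edge_width)
    persistent = edge & (rng.random(depth.shape) < nm.dropout_prob)
    frames = np.empty((n_frames,) + depth.shape, dtype=float)
    for i in range(n_frames):
        f = depth.copy()
        deviate = rng.random(depth.shape) < nm.jitter_prob
        if nm.jitter_range > 0:
            mag = rng.integers(1, nm.jitter_range + 1, size=depth.shape)
            sign = rng.choice([-1.0, 1.0], size=depth.shape)
            f = np.where(deviate & (f > 0), f + sign * mag, f)
        transient = edge & (rng.random(depth.shape) < nm.dropout_prob)
        f[transient | persistent] = 0.0
        f[depth == 0] = 0.0
        frames[i] = np.maximum(f, 0.0)
    return frames


@dataclass
class MealPair:
    """A pre/post-meal synthetic capture pair with exact ground truth."""

    pre: RenderedScene
    post: RenderedScene
    background: np.ndarray            # corrected empty-table depth (no zeros)
    pre_stack: np.ndarray
    post_stack: np.ndarray
    background_stack: np.ndarray
    gt_intake_cm3: dict[int, float]
    intrinsics: CameraIntrinsics


def make_meal_pair(pre_spec: SceneSpec,
                   intake_fractions: dict[int, float],
                   intr: CameraIntrinsics,
                   *,
                   translate_px: tuple[float, float] = (0.0, 0.0),
                   rotate_deg: float = 0.0,
                   noise: NoiseModel | None = None,
                   n_frames: int = 30,
                   rng: np.random.Generator | None = None) -> MealPair:
    """Render a pre/post-meal pair with known per-food intake.

    The post-meal scene reduces each food's volume by its intake fraction
    (heights/fill shrink; footprints stay) and rigidly moves the plate with
    everything on it by ``translate_px`` (pixels at plate-top depth) and
    ``rotate_deg`` about the plate center.  With a noise model, each capture
    becomes an ``n_frames`` stack; otherwise single noiseless frames.
    """
    if pre_spec.plate is None:
        raise ValueError("a meal pair needs a plate to align on")
    for rid, frac in intake_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"intake fraction for region {rid} must be in [0, 1]")
    plate_top = pre_spec.table_depth - pre_spec.plate.height
    mm_per_px = plate_top / intr.f
    dx_mm = translate_px[0] * mm_per_px
    dy_mm = translate_px[1] * mm_per_px

    post_solids = []
    for s in pre_spec.solids:
        frac = intake_fractions.get(s.region_id, 0.0)
        post_solids.append(s.reduced(frac) if frac > 0 else s)
    post_spec = SceneSpec(pre_spec.table_depth, pre_spec.plate, post_solids)
    post_spec = post_spec.shifted(dx_mm, dy_mm, rotate_deg)

    pre = render_scene(pre_spec, intr)
    post = render_scene(post_spec, intr)
    gt = {rid: pre.volumes_cm3[rid] - post.volumes_cm3[rid]
          for rid in pre.volumes_cm3}
    background = np.full(intr.shape, pre_spec.table_depth, dtype=float)

    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        pre_stack = apply_noise(pre.depth, noise, n_frames, rng)
        post_stack = apply_noise(post.depth, noise, n_frames, rng)
        bg_nm = replace(noise, dropout_prob=0.0)   # featureless table: jitter only
        bg_stack = apply_noise(background, bg_nm, n_frames, rng)
    else:
        pre_stack = pre.depth[None]
        post_stack = post.depth[None]
        bg_stack = background[None]
    return MealPair(pre=pre, post=post, background=background,
                    pre_stack=pre_stack, post_stack=post_stack,
                    background_stack=bg_stack, gt_intake_cm3=gt,
                    intrinsics=intr)


def load_scene_spec(path: str | Path) -> SceneSpec:
    """Load a SceneSpec from YAML/JSON: table_depth, plate{...}, solids[{shape: ...}]."""
    data = yaml.safe_load(Path(path).read_text())
    plate = Plate(**data["plate"]) if data.get("plate") else None
    shapes = {"cuboid": Cuboid, "cylinder": Cylinder,
              "bowl": BowlWithFill, "heightmap": HeightMapSolid}
    solids = []
    for entry in data.get("solids", []):
        entry = dict(entry)
        cls = shapes[entry.pop("shape")]
        solids.append(cls(**entry))
    return SceneSpec(table_depth=float(data.get("table_depth", 400.0)),
                     plate=plate, solids=solids)
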