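import numpy as np
import pytest
from skimage.transform import ProjectiveTransform

from mealdepth import (align_post_meal, apply_homography, compute_iou,
                       estimate_homography, find_plate_corners, warp_image)
from mealdepth.errors import DegenerateRegionError, NonInvertibleError


def brute_force_min_rect(mask):
    """Orientation-sweep oracle for the minimum-area enclosing rectangle."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    best = (np.inf, None)
    for theta in np.arange(0, 90, 0.05):
        th = np.deg2rad(theta)
        rot = pts @ np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if w * h < best[0]:
            best = (w * h, theta)
    return best


def rect_area(corners):
    e1 = np.linalg.norm(corners[1] - corners[0])
    e2 = np.linalg.norm(corners[2] - corners[1])
    return e1 * e2


class TestPlateCorners:
    def test_axis_aligned_rectangle_returns_own_corners(self):
        mask = np.zeros((100, 150), bool)
        mask[10:70, 10:110] = True   # corners (10,10)-(109,69)
        corners = find_plate_corners(mask)
        expected = np.array([[10, 10], [109, 10], [109, 69], [10, 69]], float)
        assert np.allclose(corners, expected, atol=1e-6)

    @pytest.mark.parametrize("angle", [45.0, 30.0])
    def test_rotated_square_matches_brute_force(self, angle):
        n = 200
        yy, xx = np.mgrid[0:n, 0:n]
        th = np.deg2rad(angle)
        u = np.cos(th) * (xx - 100) + np.sin(th) * (yy - 100)
        v = -np.sin(th) * (xx - 100) + np.cos(th) * (yy - 100)
        mask = (np.abs(u) <= 40) & (np.abs(v) <= 40)
        corners = find_plate_corners(mask)
        oracle_area, _ = brute_force_min_rect(mask)
        assert rect_area(corners) == pytest.approx(oracle_area, rel=0.01)
        # vertices sit on the mask's rotated diagonal axes, within pixelation
        d = np.linalg.norm(corners - [100, 100], axis=1)
        assert np.all(np.abs(d - d.mean()) < 1.5)

    def test_filled_circle_gives_square_of_side_diameter(self):
        n = 240
        yy, xx = np.mgrid[0:n, 0:n]
        r = 70
        mask = (xx - 120) ** 2 + (yy - 120) ** 2 <= r ** 2
        corners = find_plate_corners(mask)
        area = rect_area(corners)
        oracle_area, _ = brute_force_min_rect(mask)
        assert area == pytest.approx(oracle_area, rel=0.01)
        assert area == pytest.approx((2 * r) ** 2, rel=0.02)

    def test_corner_ordering_clockwise_from_origin(self):
        mask = np.zeros((100, 100), bool)
        mask[20:60, 30:80] = True
        c = find_plate_corners(mask)
        assert np.allclose(c[0], [30, 20])        # nearest image origin
        e1, e2 = c[1] - c[0], c[2] - c[1]
        cross = e1[0] * e2[1] - e1[1] * e2[0]
        assert cross > 0                          # clockwise with y down

    @pytest.mark.parametrize("mask", [
        np.zeros((20, 20), bool),
        np.eye(20, dtype=bool),                   # collinear diagonal
    ])
    def test_degenerate_masks_rejected(self, mask):
        with pytest.raises(DegenerateRegionError):
            find_plate_corners(mask)


class TestHomography:
    def test_identity(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        H = estimate_homography(pts, pts)
        assert np.allclose(H, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        src = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        dst = src + [5, -3]
        H = estimate_homography(src, dst)
        expected = np.array([[1, 0, 5], [0, 1, -3], [0, 0, 1]], float)
        assert np.allclose(H, expected, atol=1e-9)

    def test_random_quadrilaterals_reproduce_correspondences(self):
        rng = np.random.default_rng(11)
        src = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) * 100
        for _ in range(50):
            dst = src + rng.uniform(-20, 20, src.shape)
            H = estimate_homography(src, dst)
            mapped = apply_homography(H, src)
            assert np.abs(mapped - dst).max() < 1e-6

    def test_matches_independent_estimator(self):
        rng = np.random.default_rng(3)
        src = np.array([[10, 10], [200, 30], [220, 180], [20, 160]], float)
        dst = src + rng.uniform(-15, 15, src.shape)
        H = estimate_homography(src, dst)
        tform = ProjectiveTransform.from_estimate(src, dst)
        assert np.allclose(H, tform.params / tform.params[2, 2], atol=1e-8)

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [0, 1]], float)
        dst = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        with pytest.raises(NonInvertibleError):
            estimate_homography(src, dst)


class TestWarp:
    def test_identity_leaves_image_unchanged(self):
        rng = np.random.default_rng(0)
        img = rng.integers(300, 500, (40, 60)).astype(float)
        assert np.array_equal(warp_image(img, np.eye(3)), img)

    def test_translation_moves_depth_and_zeros_border(self):
        img = np.full((30, 30), 400.0)
        H = np.array([[1, 0, 5], [0, 1, 0], [0, 0, 1]], float)
        out = warp_image(img, H, method="nearest")
        assert np.all(out[:, :5] == 0)       # exposed border
        assert np.all(out[:, 5:] == 400.0)

    def test_roundtrip_recovers_interior(self, small_intr):
        # depth images are piecewise smooth, so double nearest-neighbor
        # resampling relocates pixels only across region boundaries
        from mealdepth import Cuboid, Cylinder, SceneSpec, render_scene
        img = render_scene(SceneSpec(solids=[
            Cuboid(0, 0, 60, 50, 30, region_id=1, on_plate=False),
            Cylinder(40, 20, 25, 15, region_id=2, on_plate=False)]),
            small_intr).depth
        th = np.deg2rad(7)
        H = np.array([[np.cos(th), -np.sin(th), 4],
                      [np.sin(th), np.cos(th), -2], [0, 0, 1]])
        back = warp_image(warp_image(img, H), np.linalg.inv(H))
        interior = np.zeros_like(img, bool)
        interior[15:-15, 15:-15] = True
        match = (back == img) & interior
        assert match.sum() / interior.sum() >= 0.99


class TestAlignPostMeal:
    def test_rigidly_moved_plate_realigned(self, full_intr):
        from mealdepth import Plate, SceneSpec, make_meal_pair
        spec = SceneSpec(plate=Plate(), solids=[])
        pair = make_meal_pair(spec, {}, full_intr, translate_px=(18, -7), rotate_deg=8.0)
        res = align_post_meal(pair.pre.plate_mask, pair.post.plate_mask)
        assert abs(np.linalg.det(res.H)) > 1e-6
        iou = compute_iou(pair.pre.plate_mask, res.plate_mask)
        assert iou >= 0.98

    def test_manual_corner_override(self):
        pre = np.zeros((60, 80), bool)
        pre[10:50, 10:70] = True
        post = np.roll(pre, 3, axis=1)
        corners = np.array([[10, 10], [69, 10], [69, 49], [10, 49]], float)
        res = align_post_meal(pre, post, pre_corners=corners,
                              post_corners=corners + [3, 0])
        assert np.allclose(res.H[:2, 2], [-3, 0], atol=1e-9)
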