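import numpy as np
import pytest

from mealdepth import (BowlWithFill, Cuboid, Cylinder, HeightMapSolid,
                       NoiseModel, Plate, SceneSpec, apply_noise,
                       make_meal_pair, render_scene, space_volume,
                       temporal_mode)
from mealdepth.synth import load_scene_spec


class TestAnalyticVolumes:
    @pytest.mark.parametrize("solid,expected_cm3", [
        (Cuboid(0, 0, 124, 126, 75), 1171.80),
        (Cuboid(0, 0, 250, 250, 50), 3125.00),
        (Cylinder(0, 0, 46, 132), 877.48),
        (Cylinder(0, 0, 66, 168), 2299.04),
    ])
    def test_reference_object_volumes(self, solid, expected_cm3):
        assert round(solid.volume_cm3, 2) == expected_cm3

    def test_bowl_fill_volume(self):
        bowl = BowlWithFill(0, 0, 50, 55, 40, 6, fill_height=20)
        assert bowl.volume_cm3 == pytest.approx(np.pi * 2500 * 20 / 1000)

    def test_heightmap_bilinear_integral(self):
        h = np.zeros((3, 3))
        h[1, 1] = 8.0        # pyramid over a 2x2-cell grid, spacing 10
        s = HeightMapSolid(0, 0, 10.0, tuple(map(tuple, h)))
        # each of 4 cells has corner mean 2.0 -> V = 4 * 2 * 100 = 800 mm^3
        assert s.volume_cm3 == pytest.approx(0.8)


class TestRenderScene:
    def test_table_only_is_constant(self, small_intr):
        scene = render_scene(SceneSpec(table_depth=400.0), small_intr)
        assert np.all(scene.depth == 400.0)
        assert not scene.food_mask.region_ids

    def test_flat_top_solid_has_two_depth_levels(self, small_intr):
        spec = SceneSpec(solids=[Cuboid(0, 0, 80, 60, 30, region_id=1, on_plate=False)])
        scene = render_scene(spec, small_intr)
        interior = scene.food_mask.region(1)
        # erode the silhouette to stay away from side-wall pixels
        from scipy.ndimage import binary_erosion
        core = binary_erosion(interior, iterations=3)
        values = np.unique(scene.depth[core | (scene.depth == 400.0)])
        assert set(values) == {370.0, 400.0}

    def test_perspective_footprint_wider_than_orthographic(self, small_intr):
        # a tall solid's silhouette exceeds its base footprint in pixels
        tall = Cuboid(30, 0, 40, 40, 60, region_id=1, on_plate=False)
        short = Cuboid(30, 0, 40, 40, 5, region_id=2, on_plate=False)
        a = render_scene(SceneSpec(solids=[tall]), small_intr).food_mask.region(1).sum()
        b = render_scene(SceneSpec(solids=[short]), small_intr).food_mask.region(2).sum()
        assert a > b * 1.2

    @pytest.mark.parametrize("height", [75.0, 10.0])
    def test_background_subtraction_measures_frustum_slab(self, full_intr, height):
        # differencing a single object against the empty table over its
        # silhouette ROI yields the view-frustum slab between the top face and
        # the table: the solid volume plus the perspective wedge along its
        # sides, A*(D^3 - Zt^3)/(3*Zt^2) for a flat-topped prism
        spec = SceneSpec(solids=[Cuboid(0, 0, 124, 126, height, region_id=1,
                                        on_plate=False)])
        scene = render_scene(spec, full_intr)
        roi = scene.food_mask.region(1)
        obj = space_volume(scene.depth, roi, full_intr).volume_cm3
        table = space_volume(np.full(full_intr.shape, 400.0), roi, full_intr).volume_cm3
        zt = 400.0 - height
        slab = 124 * 126 * (400.0 ** 3 - zt ** 3) / (3 * zt ** 2) / 1000.0
        assert table - obj == pytest.approx(slab, rel=0.02)
        assert table - obj >= spec.solids[0].volume_cm3   # wedge is non-negative

    def test_solid_outside_frustum_rejected(self, small_intr):
        spec = SceneSpec(solids=[Cuboid(500, 0, 40, 40, 20, on_plate=False)])
        with pytest.raises(ValueError, match="frustum"):
            render_scene(spec, small_intr)

    def test_plate_mask_excludes_occluding_food(self, small_intr):
        spec = SceneSpec(plate=Plate(length=200, width=160),
                         solids=[Cuboid(0, 0, 60, 50, 20, region_id=1)])
        scene = render_scene(spec, small_intr)
        assert not (scene.plate_mask & scene.food_mask.region(1)).any()
        assert scene.plate_mask.sum() > 0


class TestNoise:
    def test_seed_fixes_all_randomness(self, small_intr):
        depth = render_scene(SceneSpec(solids=[Cylinder(0, 0, 40, 25, region_id=1,
                                                        on_plate=False)]),
                             small_intr).depth
        nm = NoiseModel(seed=99)
        s1 = apply_noise(depth, nm, n_frames=5)
        s2 = apply_noise(depth, nm, n_frames=5)
        assert np.array_equal(s1, s2)

    def test_temporal_mode_recovers_noiseless_image(self, small_intr):
        depth = render_scene(SceneSpec(solids=[Cylinder(0, 0, 40, 25, region_id=1,
                                                        on_plate=False)]),
                             small_intr).depth
        nm = NoiseModel(jitter_range=1, dropout_prob=0.0, seed=4)
        stack = apply_noise(depth, nm, n_frames=30)
        recovered = temporal_mode(stack)
        assert (recovered == depth).mean() >= 0.999

    def test_dropout_confined_to_edges(self, small_intr):
        depth = render_scene(SceneSpec(solids=[Cuboid(0, 0, 60, 60, 30, region_id=1,
                                                      on_plate=False)]),
                             small_intr).depth
        nm = NoiseModel(jitter_prob=0.0, dropout_prob=0.5, edge_width=2, seed=1)
        stack = apply_noise(depth, nm, n_frames=3)
        zeros = stack == 0
        # the flat table far from the object must never drop out
        assert not zeros[:, :20, :20].any()
        assert zeros.any()


class TestMealPair:
    def test_ground_truth_intake_is_exact_difference(self, full_intr, mixed_meal_scene):
        pair = make_meal_pair(mixed_meal_scene, {1: 0.3, 2: 0.6}, full_intr)
        for rid, frac in ((1, 0.3), (2, 0.6)):
            pre_v = pair.pre.volumes_cm3[rid]
            post_v = pair.post.volumes_cm3[rid]
            assert pair.gt_intake_cm3[rid] == pytest.approx(pre_v - post_v, abs=1e-9)
            assert pair.gt_intake_cm3[rid] == pytest.approx(frac * pre_v, rel=1e-9)

    def test_plate_rigidly_moved(self, full_intr, low_cuboid_scene):
        pair = make_meal_pair(low_cuboid_scene, {1: 0.0}, full_intr,
                              translate_px=(12, 4), rotate_deg=6.0)
        assert pair.post.spec.plate.angle_deg == pytest.approx(6.0)
        assert not np.array_equal(pair.pre.plate_mask, pair.post.plate_mask)

    def test_invalid_fraction_rejected(self, full_intr, low_cuboid_scene):
        with pytest.raises(ValueError):
            make_meal_pair(low_cuboid_scene, {1: 1.4}, full_intr)


class TestSpecIO:
    def test_yaml_scene_roundtrip(self, tmp_path):
        (tmp_path / "scene.yaml").write_text(
            "table_depth: 400\n"
            "plate: {length: 280, width: 220, height: 10}\n"
            "solids:\n"
            "  - {shape: cuboid, x: 0, y: 0, length: 124, width: 126, height: 75, region_id: 1}\n"
            "  - {shape: cylinder, x: -80, y: 0, radius: 30, height: 20, region_id: 2}\n")
        spec = load_scene_spec(tmp_path / "scene.yaml")
        assert spec.plate.length == 280
        assert round(spec.solids[0].volume_cm3, 2) == 1171.80
        assert spec.solids[1].radius == 30
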