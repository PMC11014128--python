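import numpy as np
import pytest

from mealdepth import (BowlWithFill, CameraIntrinsics, Cuboid, HeightMapSolid,
                       Plate, SceneSpec)


@pytest.fixture(scope="session")
def full_intr():
    """Intrinsics of the reference capture setup (640x480, top-down at 40 cm)."""
    return CameraIntrinsics(f=598.05, cx=319.48, cy=241.50, width=640, height=480)


@pytest.fixture(scope="session")
def small_intr():
    """Reduced-resolution intrinsics for fast unit tests."""
    return CameraIntrinsics(f=200.0, cx=80.0, cy=60.0, width=160, height=120)


def dome_heights(n=41, peak=25.0):
    """Corner grid of a paraboloid mound tapering to 0 at the footprint edge."""
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = ((xx - (n - 1) / 2) ** 2 + (yy - (n - 1) / 2) ** 2) / ((n // 2) ** 2)
    return np.maximum(0.0, peak * (1 - r2))


@pytest.fixture(scope="session")
def water_bowl_scene():
    """Deep bowl holding 200 cm^3 of water on a plate (pre-meal state)."""
    fill = 200000 / (np.pi * 55 ** 2)
    bowl = BowlWithFill(0, 0, inner_radius=55, outer_radius=60, height=55,
                        base_thickness=6, fill_height=fill, region_id=1)
    return SceneSpec(plate=Plate(), solids=[bowl])


@pytest.fixture(scope="session")
def mixed_meal_scene():
    """A tapered mound and a shallow soup bowl, off plate center."""
    dome = HeightMapSolid(-60, 20, 2.5, tuple(map(tuple, dome_heights())), region_id=1)
    bowl = BowlWithFill(70, -20, 50, 55, height=30, base_thickness=6,
                        fill_height=150000 / (np.pi * 50 ** 2), region_id=2)
    return SceneSpec(plate=Plate(), solids=[dome, bowl])


@pytest.fixture(scope="session")
def low_cuboid_scene():
    """A 90 cm^3 low-profile block food (100 x 75 x 12 mm) on a plate."""
    return SceneSpec(plate=Plate(), solids=[Cuboid(0, 0, 100, 75, 12, region_id=1)])
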