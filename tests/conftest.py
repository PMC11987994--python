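from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import fishtrack3d as ft

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geom() -> ft.TankGeometry:
    return ft.TankGeometry()


@pytest.fixture(scope="session")
def small_scene() -> ft.SceneConfig:
    """Reduced-resolution scene for fast rendering in unit tests."""
    return ft.SceneConfig(image_size=(320, 180), fish_semi_axes_px=(16.0, 6.0))


@pytest.fixture(scope="session")
def small_params() -> ft.DetectionParams:
    """Detection parameters scaled to the 320x180 test scene."""
    return ft.DetectionParams(min_area_px=20, mask_dilate_px=3)


@pytest.fixture(scope="session")
def rendered_scene(geom, small_scene):
    """A 60 s noise-free two-view scene with known ground truth."""
    motion = ft.MotionConfig(duration_s=60, seed=7)
    gt = ft.simulate_trajectory(motion, geom)
    front, top, ref_f, ref_t = ft.render_views(gt, small_scene, geom)
    return {"gt": gt, "front": front, "top": top,
            "ref_front": ref_f, "ref_top": ref_t,
            "cals": small_scene.calibrations(geom), "scene": small_scene}


@pytest.fixture(scope="session")
def tracked_scene(rendered_scene, small_params):
    """Detections for both views of the rendered scene (computed once)."""
    cal_f, cal_t = rendered_scene["cals"]
    det_f = ft.process_sequence(rendered_scene["front"],
                                rendered_scene["ref_front"], cal_f,
                                small_params)
    det_t = ft.process_sequence(rendered_scene["top"],
                                rendered_scene["ref_top"], cal_t,
                                small_params)
    return {**rendered_scene, "front_dets": det_f, "top_dets": det_t}


def random_mask(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """A random small binary mask with a few blobby components."""
    h = w = size
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        cv, cu = rng.uniform(8, h - 8), rng.uniform(8, w - 8)
        a, b = rng.uniform(2, 10, size=2)
        th = rng.uniform(0, np.pi)
        vv, uu = np.mgrid[0:h, 0:w]
        du, dv = uu - cu, vv - cv
        ru = du * np.cos(th) + dv * np.sin(th)
        rv = -du * np.sin(th) + dv * np.cos(th)
        mask |= (ru / a) ** 2 + (rv / b) ** 2 <= 1
    return mask
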