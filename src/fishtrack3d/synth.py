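"""Synthetic ground-truth scenes: simulated fish trajectories rendered as
front/top frame pairs.

The simulator is a correlated random walk inside the tank's usable volume:
the horizontal heading performs a persistent wrapped-normal walk, the pitch
relaxes toward a depth-preference set by ``bottom_bias``, step lengths are
|N(mean_speed, speed_sd)| * dt, and walls reflect.  The renderer projects the
trajectory orthographically into the two camera views and draws the fish as
a filled dark ellipse aligned with its heading, over a lighter background,
with an optional static "camera reflection" artifact (present in every frame
*and* in the empty-tank reference, as a real reflection would be) and
optional Gaussian pixel noise.

Defaults emulate the study conditions this package targets: 1 frame/s
capture, a single dark elongated fish, per-frame displacements of roughly
5–30 px at the default working resolution (what a 1 Hz pyramidal flow
estimator can follow), and a dose response in which locomotion is suppressed
and late-phase positions aggregate near the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
from skimage.draw import ellipse as _ellipse

from .detection import Frame
from .geometry import (FRONT, TOP, MmPoint, TankGeometry, ViewCalibration,
                       mm_to_px)

DEFAULT_T0 = datetime(2024, 6, 1, 9, 0, 0)


@dataclass(frozen=True)
class MotionConfig:
    """Parameters of the correlated-random-walk trajectory model.

    mean_speed_mm_s / speed_sd
        Moments of the per-step speed draw, |N(mean, sd)|, in mm/s.  The
        defaults keep 1 s displacements in the 5–30 px band at the default
        rendering scale.
    turn_persistence
        In [0, 1): heading autocorrelation.  The per-step heading increment
        SD is (1 - persistence) * pi, so 0 is near-uniform turning and values
        near 1 give smooth, roaming paths.
    bottom_bias
        In [-1, 1]: preferred pitch of travel; +1 drives toward the tank
        bottom, -1 toward the water surface, 0 is depth-neutral.
    """

    duration_s: float = 600.0
    dt_s: float = 1.0
    mean_speed_mm_s: float = 15.0
    speed_sd: float = 4.0
    turn_persistence: float = 0.8
    bottom_bias: float = 0.0
    wall_margin_mm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0 or not self.dt_s > 0:
            raise ValueError("duration_s and dt_s must be positive")
        if self.mean_speed_mm_s < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if not 0 <= self.turn_persistence < 1:
            raise ValueError("turn_persistence must be in [0, 1)")
        if not -1 <= self.bottom_bias <= 1:
            raise ValueError("bottom_bias must be in [-1, 1]")


@dataclass
class StaticArtifact:
    """A constant scene element (e.g. the camera's faint glass reflection)."""

    center_px: tuple[float, float] = (60.0, 40.0)   # (u, v) in the view image
    radius_px: float = 12.0
    intensity: float = 100.0
    view: str = FRONT


@dataclass
class SceneConfig:
    """Rendering parameters for the two orthographic camera views.

    Frames are single-scene grayscale stored as 3-channel 8-bit images.  The
    fish is a filled ellipse of the given semi-axes (px), oriented along its
    instantaneous heading as projected into each view, at least 20 intensity
    levels away from the background.
    """

    image_size: tuple[int, int] = (640, 360)        # (W, H), both views
    fish_semi_axes_px: tuple[float, float] = (30.0, 11.0)
    fish_intensity: float = 40.0
    background_intensity: float = 120.0
    noise_sd: float = 0.0
    artifact: Optional[StaticArtifact] = field(default_factory=StaticArtifact)
    t0: datetime = DEFAULT_T0

    def __post_init__(self) -> None:
        if abs(self.fish_intensity - self.background_intensity) < 20:
            raise ValueError("fish must differ from background by >= 20 levels")

    def calibrations(self, geom: TankGeometry) -> tuple[ViewCalibration, ViewCalibration]:
        """Full-frame calibrations for the two views at this image size."""
        w, h = self.image_size
        roi = (0, 0, w, h)
        return (ViewCalibration.for_tank(FRONT, roi, geom),
                ViewCalibration.for_tank(TOP, roi, geom))


@dataclass
class GroundTruth:
    """Simulated trajectory plus (after rendering) the projected centroids."""

    t_s: np.ndarray                      # (N,)
    pos_mm: np.ndarray                   # (N, 3): x, y, z
    total_distance_mm: float             # sum of 3D step distances
    headings: np.ndarray                 # (N, 3) unit travel directions
    front_px: Optional[np.ndarray] = None   # (N, 2) rendered centroid (u, v)
    top_px: Optional[np.ndarray] = None


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return lo + v


def simulate_trajectory(m: MotionConfig, geom: TankGeometry) -> GroundTruth:
    """Simulate a bounded correlated random walk; reproducible per seed.

    Returns one position per time step (``t = 0, dt, ...``); the reported
    total distance is the sum of 3D distances between consecutive positions,
    i.e. exactly what an ideal point tracker would integrate.
    """
    rng = np.random.default_rng(m.seed)
    n = int(round(m.duration_s / m.dt_s))
    ext = geom.extents_xyz
    lo = [min(m.wall_margin_mm, ext[i] / 4) for i in range(3)]
    hi = [ext[i] - lo[i] for i in range(3)]

    pos = np.empty((n, 3))
    headings = np.empty((n, 3))
    pos[0] = [(lo[i] + hi[i]) / 2 for i in range(3)]
    theta = rng.uniform(0, 2 * math.pi)          # azimuth in the x-z plane
    phi = 0.0                                     # pitch; +phi moves down (-y)
    turn_sd = (1.0 - m.turn_persistence) * math.pi
    phi_target = m.bottom_bias * (math.pi / 5)
    headings[0] = [math.cos(phi) * math.cos(theta), -math.sin(phi),
                   math.cos(phi) * math.sin(theta)]
    for i in range(1, n):
        theta += rng.normal(0.0, turn_sd)
        phi = (0.7 * phi + 0.3 * phi_target
               + rng.normal(0.0, turn_sd / 3))
        phi = float(np.clip(phi, -math.pi / 3, math.pi / 3))
        step = abs(rng.normal(m.mean_speed_mm_s, m.speed_sd)) * m.dt_s
        d = np.array([math.cos(phi) * math.cos(theta),
                      -math.sin(phi),
                      math.cos(phi) * math.sin(theta)])
        cand = pos[i - 1] + step * d
        # mirror the heading at walls so the walk does not slide along them
        if cand[0] < lo[0] or cand[0] > hi[0]:
            theta = math.pi - theta
        if cand[2] < lo[2] or cand[2] > hi[2]:
            theta = -theta
        if cand[1] < lo[1] or cand[1] > hi[1]:
            phi = -phi
        for ax in range(3):
            cand[ax] = _reflect(cand[ax], lo[ax], hi[ax])
        pos[i] = cand
        delta = pos[i] - pos[i - 1]
        nrm = np.linalg.norm(delta)
        headings[i] = delta / nrm if nrm > 1e-9 else headings[i - 1]
    t_s = np.arange(n, dtype=float) * m.dt_s
    dist = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    return GroundTruth(t_s=t_s, pos_mm=pos, total_distance_mm=dist,
                       headings=headings)


def dose_profile(base: MotionConfig, suppression: float,
                 aggregation: float = 0.0) -> MotionConfig:
    """Derive a dosed-group motion config from a control config.

    ``suppression`` in [0, 1] scales the speed distribution (mean and SD) by
    (1 - suppression), matching the observed pattern that both the average
    speed and its spread shrink with dose.  ``aggregation`` in [0, 1] pulls
    the depth preference toward the water surface and tightens turning
    (smaller persistence), emulating late-phase confinement near the surface.
    """
    if not 0 <= suppression <= 1:
        raise ValueError("suppression must be in [0, 1]")
    if not 0 <= aggregation <= 1:
        raise ValueError("aggregation must be in [0, 1]")
    factor = 1.0 - suppression
    bias = (1.0 - aggregation) * base.bottom_bias - aggregation
    return replace(base,
                   mean_speed_mm_s=base.mean_speed_mm_s * factor,
                   speed_sd=base.speed_sd * factor,
                   bottom_bias=bias,
                   turn_persistence=base.turn_persistence * (1.0 - aggregation))


def _draw_scene(shape_hw: tuple[int, int], scene: SceneConfig, view: str,
                fish_px: Optional[tuple[float, float]],
                fish_angle_rad: float,
                rng: Optional[np.random.Generator]) -> np.ndarray:
    h, w = shape_hw
    img = np.full((h, w), scene.background_intensity, dtype=np.float64)
    art = scene.artifact
    if art is not None and art.view == view:
        rr, cc = _ellipse(art.center_px[1], art.center_px[0],
                          art.radius_px, art.radius_px, shape=(h, w))
        img[rr, cc] = art.intensity
    if fish_px is not None:
        a, b = scene.fish_semi_axes_px
        # skimage's rotation convention for ellipse() is clockwise in (row,
        # col); negate to orient the long axis along the (u, v) heading angle.
        rr, cc = _ellipse(fish_px[1], fish_px[0], b, a,
                          rotation=-fish_angle_rad, shape=(h, w))
        img[rr, cc] = scene.fish_intensity
    if rng is not None and scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _to_frame(gray: np.ndarray, ts: datetime, view: str) -> Frame:
    return Frame(pixels=np.repeat(gray[:, :, None], 3, axis=2),
                 timestamp=ts, view=view)


def render_views(gt: GroundTruth, scene: SceneConfig, geom: TankGeometry,
                 noise_seed: int = 0
                 ) -> tuple[list[Frame], list[Frame], Frame, Frame]:
    """Render the trajectory into (front frames, top frames, refs).

    Fills ``gt.front_px`` / ``gt.top_px`` with the projected fish centres.
    The reference frames contain the artifact but no fish, exactly as an
    empty-tank reference would.  Noise, when enabled, is freshly drawn per
    frame (references included) from ``noise_seed``.
    """
    cal_f, cal_t = scene.calibrations(geom)
    w, h = scene.image_size
    rng = np.random.default_rng(noise_seed) if scene.noise_sd > 0 else None
    front, top = [], []
    n = len(gt.t_s)
    gt.front_px = np.empty((n, 2))
    gt.top_px = np.empty((n, 2))
    for i in range(n):
        x, y, z = gt.pos_mm[i]
        p_f = mm_to_px(cal_f, geom, MmPoint(x_mm=x, y_mm=y))
        p_t = mm_to_px(cal_t, geom, MmPoint(x_mm=x, z_mm=z))
        gt.front_px[i] = (p_f.u, p_f.v)
        gt.top_px[i] = (p_t.u, p_t.v)
        hx, hy, hz = gt.headings[i]
        # project the heading into each view's (u, v) axes (front v is
        # flipped: up in the tank is up in the image)
        ang_f = math.atan2(-hy * cal_f.px_per_mm_v, hx * cal_f.px_per_mm_u)
        ang_t = math.atan2(hz * cal_t.px_per_mm_v, hx * cal_t.px_per_mm_u)
        ts = scene.t0 + timedelta(seconds=float(gt.t_s[i]))
        front.append(_to_frame(
            _draw_scene((h, w), scene, FRONT, (p_f.u, p_f.v), ang_f, rng),
            ts, FRONT))
        top.append(_to_frame(
            _draw_scene((h, w), scene, TOP, (p_t.u, p_t.v), ang_t, rng),
            ts, TOP))
    ref_f = _to_frame(_draw_scene((h, w), scene, FRONT, None, 0.0, rng),
                      scene.t0 - timedelta(seconds=60), FRONT)
    ref_t = _to_frame(_draw_scene((h, w), scene, TOP, None, 0.0, rng),
                      scene.t0 - timedelta(seconds=60), TOP)
    return front, top, ref_f, ref_t
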