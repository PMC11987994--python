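"""Tank geometry and per-view pixel <-> millimetre calibration.

Coordinate conventions shared by every other module:

* Tank frame: right-handed, origin at the front-left-bottom corner of the
  tank.  ``x`` runs along the tank's long side (width), ``y`` up from the
  bottom, ``z`` along the short side (depth).  The usable ``y`` range is the
  water column, not the full wall height.
* Pixels: 0-based, continuous.  Pixel ``(u, v)`` covers the half-open square
  ``[u, u+1) x [v, v+1)``; the point ``(u+0.5, v+0.5)`` is its centre.  ``u``
  grows rightward, ``v`` grows downward (image convention).
* A region of interest (ROI) is a half-open rectangle ``(u0, v0, u1, v1)`` in
  source-image pixels; all detection output is in ROI-local coordinates.

The front camera sees the tank's long side as the image ``u`` axis (-> x) and
the water column as ``v`` (-> y, flipped: the top image row is the water
surface).  The top camera sees the long side as ``u`` (-> x) and the short
side as ``v`` (-> z).

Calibration is a per-axis linear scale from ROI extent to tank extent.  No
lens or water-refraction model is applied; with the cameras far from a small
tank the residual is treated as part of the measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

logger = logging.getLogger(__name__)

FRONT = "front"
TOP = "top"
VIEWS = (FRONT, TOP)


class ConfigError(ValueError):
    """A geometry/calibration configuration value is invalid."""


class CoordinateError(ValueError):
    """A point lies outside the region it must belong to."""


@dataclass(frozen=True)
class TankGeometry:
    """Physical extents of the rectangular glass tank, in millimetres.

    Defaults describe a 54 x 37 x 40 cm tank filled to a 20 cm water column,
    so the fish's usable volume is 540 (x) x 200 (y) x 370 (z) mm.
    """

    width_mm: float = 540.0   # x extent (long side)
    depth_mm: float = 370.0   # z extent (short side)
    height_mm: float = 400.0  # glass wall height
    water_mm: float = 200.0   # water column height; usable y extent

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "height_mm", "water_mm"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"TankGeometry.{name} must be > 0")
        if self.water_mm > self.height_mm:
            raise ConfigError("water_mm cannot exceed height_mm")

    @property
    def extents_xyz(self) -> tuple[float, float, float]:
        """Usable (x, y, z) extents in mm; y is the water column."""
        return (self.width_mm, self.water_mm, self.depth_mm)


@dataclass(frozen=True)
class ViewCalibration:
    """Linear pixel->mm mapping for one camera view.

    ``roi`` is the crop rectangle ``(u0, v0, u1, v1)`` in source pixels,
    half-open.  ``px_per_mm_u`` / ``px_per_mm_v`` scale the two image axes
    independently (the ROI need not preserve the tank's aspect ratio).
    ``v_flip`` marks views where the image v axis points opposite to the tank
    axis it measures; for the front view the tank bottom is at the ROI's
    bottom edge, so v_flip is normally true there.
    """

    view: str
    roi: tuple[int, int, int, int]
    px_per_mm_u: float
    px_per_mm_v: float
    v_flip: bool = False

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ConfigError(f"view must be one of {VIEWS}, got {self.view!r}")
        u0, v0, u1, v1 = self.roi
        if not (u1 > u0 and v1 > v0):
            raise ConfigError(f"degenerate ROI {self.roi}")
        if min(u0, v0) < 0:
            raise ConfigError(f"ROI {self.roi} has negative origin")
        if not (self.px_per_mm_u > 0 and self.px_per_mm_v > 0):
            raise ConfigError("pixel scales must be strictly positive")

    @property
    def width_px(self) -> int:
        return self.roi[2] - self.roi[0]

    @property
    def height_px(self) -> int:
        return self.roi[3] - self.roi[1]

    @classmethod
    def for_tank(
        cls,
        view: str,
        roi: tuple[int, int, int, int],
        geom: TankGeometry,
        v_flip: Optional[bool] = None,
    ) -> "ViewCalibration":
        """Build a calibration whose ROI spans the full tank face.

        The front view maps the ROI to width x water column; the top view to
        width x depth.  ``v_flip`` defaults to true for the front view (image
        v downward, tank y upward) and false for the top view.
        """
        u0, v0, u1, v1 = roi
        w_px, h_px = u1 - u0, v1 - v0
        if view == FRONT:
            scale_u = w_px / geom.width_mm
            scale_v = h_px / geom.water_mm
            flip = True if v_flip is None else v_flip
        elif view == TOP:
            scale_u = w_px / geom.width_mm
            scale_v = h_px / geom.depth_mm
            flip = False if v_flip is None else v_flip
        else:
            raise ConfigError(f"view must be one of {VIEWS}, got {view!r}")
        return cls(view=view, roi=tuple(roi), px_per_mm_u=scale_u,
                   px_per_mm_v=scale_v, v_flip=flip)


@dataclass(frozen=True)
class PxPoint:
    """Continuous ROI-local pixel coordinates (origin: ROI top-left)."""

    u: float
    v: float


@dataclass(frozen=True)
class MmPoint:
    """Tank-frame point carrying the axes one view can measure.

    The front view yields (x_mm, y_mm); the top view (x_mm, z_mm); a fused
    track point carries all three.
    """

    x_mm: Optional[float] = None
    y_mm: Optional[float] = None
    z_mm: Optional[float] = None


def _mm_extents(cal: ViewCalibration, geom: TankGeometry) -> tuple[float, float]:
    """(extent along image u, extent along image v) in mm for this view."""
    if cal.view == FRONT:
        return geom.width_mm, geom.water_mm
    return geom.width_mm, geom.depth_mm


def _clamp(value: float, lo: float, hi: float, what: str) -> float:
    if value < lo or value > hi:
        clamped = min(max(value, lo), hi)
        logger.warning("clamped %s from %.3f to %.3f (range [%g, %g])",
                       what, value, clamped, lo, hi)
        return clamped
    return value


def px_to_mm(cal: ViewCalibration, geom: TankGeometry, p: PxPoint) -> MmPoint:
    """Map an ROI-local pixel point to millimetre tank coordinates.

    The point must lie within the ROI (the closed rectangle
    ``[0, width_px] x [0, height_px]`` in continuous coordinates).  Mapped
    coordinates are clamped to the tank extents; clamping is logged, not an
    error, because edge detections may overshoot the glass by a pixel.
    """
    if not (0 <= p.u <= cal.width_px and 0 <= p.v <= cal.height_px):
        raise CoordinateError(
            f"point ({p.u}, {p.v}) outside ROI "
            f"[0, {cal.width_px}] x [0, {cal.height_px}]")
    ext_u, ext_v = _mm_extents(cal, geom)
    mm_u = p.u / cal.px_per_mm_u
    mm_v = p.v / cal.px_per_mm_v
    if cal.v_flip:
        mm_v = ext_v - mm_v
    mm_u = _clamp(mm_u, 0.0, ext_u, f"{cal.view} u-axis mm")
    mm_v = _clamp(mm_v, 0.0, ext_v, f"{cal.view} v-axis mm")
    if cal.view == FRONT:
        return MmPoint(x_mm=mm_u, y_mm=mm_v)
    return MmPoint(x_mm=mm_u, z_mm=mm_v)


def mm_to_px(cal: ViewCalibration, geom: TankGeometry, m: MmPoint) -> PxPoint:
    """Inverse of :func:`px_to_mm`; used mainly by the synthetic renderer."""
    ext_u, ext_v = _mm_extents(cal, geom)
    if cal.view == FRONT:
        mm_u, mm_v = m.x_mm, m.y_mm
    else:
        mm_u, mm_v = m.x_mm, m.z_mm
    if mm_u is None or mm_v is None:
        raise CoordinateError(f"MmPoint {m} lacks the axes of view {cal.view!r}")
    if not (0 <= mm_u <= ext_u and 0 <= mm_v <= ext_v):
        raise CoordinateError(
            f"mm point ({mm_u}, {mm_v}) outside tank extents "
            f"[0, {ext_u}] x [0, {ext_v}] for view {cal.view!r}")
    if cal.v_flip:
        mm_v = ext_v - mm_v
    return PxPoint(u=mm_u * cal.px_per_mm_u, v=mm_v * cal.px_per_mm_v)
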