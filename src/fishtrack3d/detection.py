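"""Per-frame single-fish detection from motion energy.

The pipeline mirrors the stage sequence of the imaging protocol it
re-implements: each frame is cropped to the tank ROI, the empty-tank
reference is subtracted, the absolute difference is converted to grayscale,
dense optical flow against the previous frame yields a motion mask, and Canny
edges of the motion-gated grayscale are dilated into a solid blob whose
convex hull gives the fish's position (hull centroid), size (hull area) and
orientation (long side of the minimum-area enclosing rectangle).

Detection is motion-gated by construction: an immobile fish produces no flow
and therefore ``status="missing"``; the fusion stage carries the last known
position forward.  Static scene elements — the faint camera reflection in the
tank glass is the canonical example — are identical in frame and reference
and produce no flow, so they are never detected.

The dense flow estimator is the coarse-to-fine iterative Lucas–Kanade solver
from scikit-image.  Like polynomial-expansion flow it is a local
least-squares matcher wrapped in a Gaussian pyramid, and it handles the
5–30 px per-frame displacements a 1 Hz capture rate produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import canny as _canny
from skimage.registration import optical_flow_ilk, phase_cross_correlation

logger = logging.getLogger(__name__)

# BT.601 luminance weights, the usual RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class FrameMismatchError(ValueError):
    """Two frames that must share shape/view do not."""


@dataclass
class Frame:
    """One captured image: 8-bit pixels, capture timestamp, camera view."""

    pixels: np.ndarray          # (H, W, 3) or (H, W) uint8
    timestamp: datetime
    view: str

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class DetectionParams:
    """Tunable knobs of the detection pipeline (ROI-resolution pixels).

    The defaults are calibrated for ~640x360 working resolution; at other
    resolutions scale ``min_area_px`` with pixel area and the rest with
    linear pixel size.

    diff_floor / denoise
        Pre-flow cleanup of the subtracted grayscale: a 3x3 median filter
        followed by zeroing values below ``diff_floor``.  Sensor noise in the
        subtracted image is uncorrelated between frames and would otherwise
        feed the flow matcher pure noise; flooring makes the empty background
        exactly flat, where the flow is identically zero.
    mag_thresh
        Flow-magnitude threshold (px/frame) of the motion mask; inclusive.
    mask_dilate_px
        Radius by which the motion mask is grown before gating the grayscale,
        so the whole fish silhouette survives the gate even where its
        interior is textureless.
    canny_on
        Whether Canny runs on the motion-gated grayscale (default) or on the
        flow-magnitude image.
    flow_downscale
        Integer factor by which the grayscale pair is block-averaged before
        the flow stage (magnitudes are rescaled so ``mag_thresh`` keeps its
        full-resolution meaning and the mask is upsampled back).  The motion
        mask is only a gate, so a factor of 2 on large frames costs no
        measurable accuracy and cuts the flow stage's cost ~4x.
    shift_gate
        Verify motion with a phase-correlation displacement estimate before
        trusting the flow field.  Local flow solvers overshoot on sub-pixel
        motion of a flat blob (rasterisation jitter looks like structure);
        the rigid-shift estimate between consecutive subtracted grayscales is
        accurate to a fraction of a pixel, so frames whose estimated shift is
        below ``mag_thresh`` are reported missing — the fish did not move.
    """

    mag_thresh: float = 1.0
    canny_lo: float = 50.0
    canny_hi: float = 150.0
    kernel_px: int = 3
    dilate_iter: int = 2
    min_area_px: float = 50.0
    diff_floor: float = 15.0
    denoise: Literal["median", "none"] = "median"
    mask_dilate_px: int = 5
    flow_radius: int = 5
    flow_num_warp: int = 3
    flow_downscale: int = 1
    canny_on: Literal["gated_gray", "flow_mag"] = "gated_gray"
    shift_gate: bool = True

    def __post_init__(self) -> None:
        if not self.mag_thresh > 0:
            raise ValueError("mag_thresh must be > 0")
        if not self.canny_lo < self.canny_hi:
            raise ValueError("canny_lo must be < canny_hi")
        if self.kernel_px < 3 or self.kernel_px % 2 == 0:
            raise ValueError("kernel_px must be odd and >= 3")
        if self.dilate_iter < 0:
            raise ValueError("dilate_iter must be >= 0")


@dataclass
class Detection:
    """Per-frame, per-view fish measurement.

    ``centroid`` is the convex-hull area centroid in continuous ROI-local
    pixel coordinates (pixel (u, v) spans [u, u+1) x [v, v+1)); ``area_px``
    the hull area; ``angle_deg`` the orientation in [0, 180) of the long side
    of the hull's minimum-area enclosing rectangle, measured from the image
    u axis toward the v axis.  When nothing qualifying moved, ``status`` is
    ``"missing"`` and the measurement fields are ``None``.
    """

    timestamp: datetime
    view: str
    status: Literal["detected", "missing"]
    centroid: Optional[tuple[float, float]] = None
    area_px: Optional[float] = None
    angle_deg: Optional[float] = None
    polygon: Optional[np.ndarray] = None   # (n, 2) hull vertices, (u, v), CCW

    @classmethod
    def missing(cls, timestamp: datetime, view: str) -> "Detection":
        return cls(timestamp=timestamp, view=view, status="missing")


def crop(frame: Frame, roi: tuple[int, int, int, int]) -> Frame:
    u0, v0, u1, v1 = roi
    h, w = frame.pixels.shape[:2]
    if not (0 <= u0 < u1 <= w and 0 <= v0 < v1 <= h):
        raise FrameMismatchError(f"ROI {roi} outside image {w}x{h}")
    return replace(frame, pixels=frame.pixels[v0:v1, u0:u1])


def subtract_reference(frame: Frame, reference: Frame) -> np.ndarray:
    """Absolute difference against the empty-tank reference, as grayscale.

    Returns a float array in [0, 255] with the frame's H x W.  Anything that
    was already present in the empty tank (walls, reflections, the air
    stone's shadow) cancels; the fish remains as a bright region.
    """
    if frame.pixels.shape != reference.pixels.shape:
        raise FrameMismatchError(
            f"frame shape {frame.pixels.shape} != reference "
            f"{reference.pixels.shape}")
    if frame.view != reference.view:
        raise FrameMismatchError(
            f"frame view {frame.view!r} != reference view {reference.view!r}")
    diff = np.abs(frame.pixels.astype(np.float64)
                  - reference.pixels.astype(np.float64))
    if diff.ndim == 3:
        diff = diff @ _LUMA
    return np.clip(diff, 0.0, 255.0)


def preclean(gray: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Denoise the subtracted grayscale and zero sub-floor residuals."""
    out = gray
    if params.denoise == "median":
        out = ndimage.median_filter(out, size=3)
    if params.diff_floor > 0:
        out = np.where(out < params.diff_floor, 0.0, out)
    return out


def dense_flow(prev: np.ndarray, cur: np.ndarray, *, radius: int = 5,
               num_warp: int = 3) -> np.ndarray:
    """Dense displacement field mapping ``prev`` onto ``cur``.

    Returns an (H, W, 2) array whose last axis is (du, dv) in pixels per
    frame.  Computed with scikit-image's pyramidal iterative Lucas–Kanade
    estimator; flat (zero-gradient) regions get zero flow.
    """
    if prev.shape != cur.shape:
        raise FrameMismatchError(f"flow shapes differ: {prev.shape} vs {cur.shape}")
    v, u = optical_flow_ilk(
        prev.astype(np.float32), cur.astype(np.float32),
        radius=radius, num_warp=num_warp, prefilter=False)
    return np.stack([u, v], axis=-1)


def flow_magnitude(flow: np.ndarray) -> np.ndarray:
    return np.hypot(flow[..., 0], flow[..., 1])


def motion_mask(flow: np.ndarray, mag_thresh: float) -> np.ndarray:
    """Binary mask of pixels whose flow magnitude is >= ``mag_thresh``."""
    if not mag_thresh > 0:
        raise ValueError("mag_thresh must be > 0")
    return flow_magnitude(flow) >= mag_thresh


def _upsample(arr: np.ndarray, factor: int,
              shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample back to ``shape``, zero-padding edges."""
    big = np.repeat(np.repeat(arr, factor, axis=0), factor, axis=1)
    out = np.zeros(shape, dtype=arr.dtype)
    h = min(shape[0], big.shape[0])
    w = min(shape[1], big.shape[1])
    out[:h, :w] = big[:h, :w]
    return out


def _block_mean(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-average downscale by an integer factor (trailing rows/cols cut)."""
    h, w = img.shape
    hh, ww = h // factor, w // factor
    return img[:hh * factor, :ww * factor].reshape(
        hh, factor, ww, factor).mean(axis=(1, 3))


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return xx * xx + yy * yy <= radius * radius


def edge_and_dilate(img: np.ndarray, canny_lo: float, canny_hi: float,
                    kernel_px: int, iterations: int) -> np.ndarray:
    """Canny edges of ``img`` dilated into a solid region.

    ``img`` may be a grayscale (float, 0..255 scale) or a binary mask; the
    dilation uses an elliptical (disk) footprint of diameter ``kernel_px``,
    applied ``iterations`` times, thick enough to close the fish outline.
    """
    if not canny_lo < canny_hi:
        raise ValueError("canny_lo must be < canny_hi")
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be odd and >= 3")
    if img.dtype == bool:
        img = img.astype(np.float64) * 255.0
    edges = _canny(img.astype(np.float64), sigma=1.0,
                   low_threshold=canny_lo, high_threshold=canny_hi)
    if iterations > 0 and edges.any():
        edges = ndimage.binary_dilation(
            edges, structure=_disk(kernel_px // 2), iterations=iterations)
    return edges


def _polygon_area_centroid(verts: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Shoelace area and area centroid of a simple polygon (n, 2)."""
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return 0.0, (float(x.mean()), float(y.mean()))
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return abs(area), (float(cx), float(cy))


def _min_rect_angle(hull_pts: np.ndarray) -> float:
    """Orientation in [0, 180) of the minimum-area rectangle's long side.

    Rotating calipers over hull edges: the minimal rectangle has a side
    collinear with some hull edge.
    """
    pts = hull_pts
    n = len(pts)
    best = (np.inf, 0.0)
    for i in range(n):
        edge = pts[(i + 1) % n] - pts[i]
        norm = np.hypot(*edge)
        if norm < 1e-12:
            continue
        d = edge / norm                       # along-edge direction
        perp = np.array([-d[1], d[0]])
        proj_d = pts @ d
        proj_p = pts @ perp
        len_d = proj_d.max() - proj_d.min()
        len_p = proj_p.max() - proj_p.min()
        area = len_d * len_p
        if area < best[0] - 1e-9:
            long_dir = d if len_d >= len_p else perp
            ang = np.degrees(np.arctan2(long_dir[1], long_dir[0])) % 180.0
            best = (area, ang)
    return float(best[1] % 180.0)


def extract_blob(mask: np.ndarray, min_area_px: float,
                 timestamp: Optional[datetime] = None,
                 view: str = "front") -> Detection:
    """Measure the largest moving blob in a binary mask.

    Selects the largest 8-connected foreground component with pixel count
    >= ``min_area_px`` (ties broken by uppermost-then-leftmost bounding-box
    origin), takes the convex hull of its pixels' corner points, and reports
    hull centroid, hull area, and the minimum-area-rectangle orientation.
    Returns a ``missing`` detection when no component qualifies.
    """
    ts = timestamp or datetime(1970, 1, 1)
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return Detection.missing(ts, view)
    counts = np.bincount(labels.ravel())[1:]   # skip background
    best_lab, best_key = None, None
    slices = ndimage.find_objects(labels)
    for lab in range(1, nlab + 1):
        if counts[lab - 1] < min_area_px:
            continue
        sl = slices[lab - 1]
        # sort key: larger area first, then uppermost, then leftmost origin
        key = (-counts[lab - 1], sl[0].start, sl[1].start)
        if best_key is None or key < best_key:
            best_key, best_lab = key, lab
    if best_lab is None:
        return Detection.missing(ts, view)
    vv, uu = np.nonzero(labels == best_lab)
    # corner points of each pixel's unit square, continuous convention
    corners = np.concatenate([
        np.stack([uu, vv], axis=1),
        np.stack([uu + 1, vv], axis=1),
        np.stack([uu, vv + 1], axis=1),
        np.stack([uu + 1, vv + 1], axis=1),
    ]).astype(np.float64)
    try:
        hull = ConvexHull(corners)
    except QhullError:   # degenerate (collinear) component
        return Detection.missing(ts, view)
    verts = corners[hull.vertices]             # CCW order
    area, centroid = _polygon_area_centroid(verts)
    angle = _min_rect_angle(verts)
    return Detection(timestamp=ts, view=view, status="detected",
                     centroid=centroid, area_px=area, angle_deg=angle,
                     polygon=verts)


def process_frame(prev: Optional[Frame], cur: Frame, reference: Frame,
                  cal, params: DetectionParams) -> Detection:
    """Full detection pipeline for one frame.

    ``cal`` is the view's :class:`~fishtrack3d.geometry.ViewCalibration`;
    frames are cropped to its ROI first.  The first frame of a sequence
    (``prev`` is None) has no motion estimate and yields ``missing``.
    """
    if prev is not None and prev.view != cur.view:
        raise FrameMismatchError(
            f"prev view {prev.view!r} != cur view {cur.view!r}")
    ref_c = crop(reference, cal.roi)
    cur_gray = preclean(subtract_reference(crop(cur, cal.roi), ref_c), params)
    if prev is None:
        return Detection.missing(cur.timestamp, cur.view)
    prev_gray = preclean(subtract_reference(crop(prev, cal.roi), ref_c), params)
    if params.shift_gate:
        shift = phase_cross_correlation(prev_gray, cur_gray, upsample_factor=8,
                                        normalization=None)[0]
        if np.hypot(*shift) < params.mag_thresh:
            return Detection.missing(cur.timestamp, cur.view)
    ds = max(1, int(params.flow_downscale))
    if ds > 1:
        flow = dense_flow(_block_mean(prev_gray, ds), _block_mean(cur_gray, ds),
                          radius=params.flow_radius,
                          num_warp=params.flow_num_warp)
        mag = _upsample(flow_magnitude(flow) * ds, ds, prev_gray.shape)
    else:
        flow = dense_flow(prev_gray, cur_gray, radius=params.flow_radius,
                          num_warp=params.flow_num_warp)
        mag = flow_magnitude(flow)
    mask = mag >= params.mag_thresh
    if not mask.any():
        return Detection.missing(cur.timestamp, cur.view)
    if params.mask_dilate_px > 0:
        mask = ndimage.binary_dilation(mask, structure=_disk(params.mask_dilate_px))
    if params.canny_on == "flow_mag":
        gated = np.where(mask, mag, 0.0)
        # flow magnitudes live on a much smaller scale than 8-bit intensities
        scale = gated.max()
        if scale > 0:
            gated = gated * (255.0 / scale)
    else:
        gated = np.where(mask, cur_gray, 0.0)
    blob = edge_and_dilate(gated, params.canny_lo, params.canny_hi,
                           params.kernel_px, params.dilate_iter)
    return extract_blob(blob, params.min_area_px,
                        timestamp=cur.timestamp, view=cur.view)


def process_sequence(frames: Sequence[Frame], reference: Frame, cal,
                     params: Optional[DetectionParams] = None) -> list[Detection]:
    """Run :func:`process_frame` over a time-ordered frame sequence."""
    params = params or DetectionParams()
    out: list[Detection] = []
    prev: Optional[Frame] = None
    for f in frames:
        out.append(process_frame(prev, f, reference, cal, params))
        prev = f
    return out
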