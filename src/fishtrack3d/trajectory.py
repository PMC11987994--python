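"""Locomotion metrics over fused 3D tracks.

Turns the per-second track into the quantities the behavioural analysis
works with: instantaneous speed (3D Euclidean step distance over the step
interval), cumulative swim distance, non-overlapping 10-second windowed mean
speeds (the statistical unit: a 10-hour, 1 Hz recording yields 36,000 speed
samples and exactly 3,600 windows), and 3D occupancy histograms over time
slices, the quantitative form of position-density plots.

Convention: the first sample's speed is 0 — speed at time ``t_i`` refers to
the displacement arriving at ``t_i``.  Carried track points (no motion
detected) duplicate the previous position, so they contribute zero speed;
measured motion is never invented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fusion import TrackPoint3D
from .geometry import TankGeometry


@dataclass
class SpeedSeries:
    """1 Hz (nominally) speeds aligned with track timestamps."""

    t_s: np.ndarray          # seconds since track start
    speed_mm_s: np.ndarray   # same length; speed_mm_s[0] == 0
    dt_s: float = 1.0


@dataclass
class WindowedSpeeds:
    """Means of consecutive non-overlapping windows of a speed series."""

    window_s: float
    means: np.ndarray        # mm/s


@dataclass
class OccupancyGrid:
    """3D position histogram over a time slice of the track."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]   # x, y, z bin edges, mm
    counts: np.ndarray                                  # (nx, ny, nz)
    slice_label: str


def track_positions(track: Sequence[TrackPoint3D]) -> np.ndarray:
    return np.array([[p.x_mm, p.y_mm, p.z_mm] for p in track], dtype=float)


def step_speeds(track: Sequence[TrackPoint3D], dt_s: float = 1.0) -> SpeedSeries:
    """Per-sample speed: 3D step distance divided by the step interval."""
    if len(track) == 0:
        return SpeedSeries(t_s=np.empty(0), speed_mm_s=np.empty(0), dt_s=dt_s)
    t = np.array([p.t_s for p in track], dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("track timestamps must be strictly increasing")
    pos = track_positions(track)
    speeds = np.zeros(len(track))
    if len(track) > 1:
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        speeds[1:] = steps / np.diff(t)
    return SpeedSeries(t_s=t, speed_mm_s=speeds, dt_s=dt_s)


def total_distance(series: SpeedSeries) -> float:
    """Total swim distance in mm: the time-integral of speed."""
    if len(series.t_s) < 2:
        return 0.0
    return float(np.sum(series.speed_mm_s[1:] * np.diff(series.t_s)))


def window_means(series: SpeedSeries, window_s: float = 10.0) -> WindowedSpeeds:
    """Non-overlapping windowed means; a trailing partial window is dropped."""
    n_per = window_s / series.dt_s
    if n_per < 1 or abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("window_s must be a positive multiple of dt_s")
    n_per = int(round(n_per))
    n_win = len(series.speed_mm_s) // n_per
    trimmed = series.speed_mm_s[:n_win * n_per]
    means = trimmed.reshape(n_win, n_per).mean(axis=1) if n_win else np.empty(0)
    return WindowedSpeeds(window_s=window_s, means=means)


def occupancy(track: Sequence[TrackPoint3D], geom: TankGeometry,
              slice_hours: Optional[tuple[float, float]] = None,
              bins_per_axis: tuple[int, int, int] = (10, 8, 8)) -> OccupancyGrid:
    """3D histogram of track positions within a time slice.

    ``slice_hours`` selects track points with ``slice[0] <= t_s/3600 <
    slice[1]``; ``None`` uses the whole track.  Bins span the tank's usable
    extents, so grids from different recordings are directly comparable.
    """
    pos = track_positions(track)
    t = np.array([p.t_s for p in track], dtype=float)
    if slice_hours is None:
        label = "all"
        sel = np.ones(len(track), dtype=bool)
    else:
        lo, hi = slice_hours
        label = f"{lo:g}-{hi:g}h"
        sel = (t >= lo * 3600.0) & (t < hi * 3600.0)
    ext = geom.extents_xyz
    edges = tuple(np.linspace(0.0, ext[i], bins_per_axis[i] + 1) for i in range(3))
    if sel.any():
        counts, _ = np.histogramdd(pos[sel], bins=edges)
    else:
        counts = np.zeros(bins_per_axis)
    return OccupancyGrid(edges=edges, counts=counts, slice_label=label)
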