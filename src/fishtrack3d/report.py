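"""Occupancy exports and 3D trajectory plots.

The report stage summarises a fused track as contiguous two-hour occupancy
slices (long-format CSV) plus a full-span slice, and renders 3D scatter
plots of the trajectory with points coloured from green (early) to red
(late), the standard way these position clouds are inspected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402
import numpy as np  # noqa: E402

from .fusion import TrackPoint3D
from .geometry import TankGeometry
from .io import occupancy_to_df, write_csv
from .trajectory import occupancy, track_positions

EARLY_LATE_CMAP = LinearSegmentedColormap.from_list(
    "early_late", ["green", "gold", "red"])


def two_hour_slices(track: Sequence[TrackPoint3D]) -> list[tuple[float, float]]:
    """All contiguous 2-hour slices covering the track's time span."""
    if not track:
        return []
    span_h = track[-1].t_s / 3600.0
    n = int(np.ceil(span_h / 2.0)) or 1
    return [(2.0 * i, 2.0 * (i + 1)) for i in range(n)]


def export_occupancy(track: Sequence[TrackPoint3D], geom: TankGeometry,
                     out_dir: Path,
                     bins_per_axis: tuple[int, int, int] = (10, 8, 8)
                     ) -> list[Path]:
    """Write per-2-h-slice occupancy CSVs plus one full-span export."""
    out_dir = Path(out_dir)
    paths = []
    for sl in two_hour_slices(track):
        grid = occupancy(track, geom, slice_hours=sl, bins_per_axis=bins_per_axis)
        paths.append(write_csv(occupancy_to_df(grid),
                               out_dir / f"occupancy_{grid.slice_label}.csv"))
    grid = occupancy(track, geom, slice_hours=None, bins_per_axis=bins_per_axis)
    paths.append(write_csv(occupancy_to_df(grid),
                           out_dir / "occupancy_all.csv"))
    return paths


def plot_track_3d(track: Sequence[TrackPoint3D], geom: TankGeometry,
                  path: Path, title: Optional[str] = None,
                  slice_hours: Optional[tuple[float, float]] = None) -> Path:
    """3D scatter of the track, coloured green (early) to red (late)."""
    pos = track_positions(track)
    t = np.array([p.t_s for p in track])
    if slice_hours is not None:
        lo, hi = slice_hours
        sel = (t >= lo * 3600.0) & (t < hi * 3600.0)
        pos, t = pos[sel], t[sel]
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    if len(t):
        rel = (t - t.min()) / max(t.max() - t.min(), 1.0)
        ax.scatter(pos[:, 0], pos[:, 2], pos[:, 1], c=rel, s=3,
                   cmap=EARLY_LATE_CMAP)
    ax.set_xlim(0, geom.width_mm)
    ax.set_ylim(0, geom.depth_mm)
    ax.set_zlim(0, geom.water_mm)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_zlabel("y (mm)")
    if title:
        ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
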