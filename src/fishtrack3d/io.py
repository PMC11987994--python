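"""Reading frame directories and writing the pipeline's CSV outputs.

Frames are still images named by their capture timestamp
(``YYYYMMDD_HHMMSS.png`` by default — the capture software used the
date-time as the filename), one directory per camera view, plus one
``reference.png`` per view taken while the tank was empty.

All CSV outputs are comma-separated UTF-8 with a header row and ``.``
decimals, fixed for reproducibility.
"""

from __future__ import annotations

import json
import logging
import time
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import Detection, Frame
from .fusion import TrackPoint3D
from .trajectory import OccupancyGrid, SpeedSeries, WindowedSpeeds

logger = logging.getLogger(__name__)

TS_FORMAT = "%Y%m%d_%H%M%S"
TS_ISO = "%Y-%m-%d %H:%M:%S"
IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def parse_frame_name(path: Path, name_format: str = TS_FORMAT) -> datetime:
    return datetime.strptime(path.stem, name_format)


def frame_filename(ts: datetime, name_format: str = TS_FORMAT,
                   ext: str = ".png") -> str:
    return ts.strftime(name_format) + ext


def list_frame_files(directory: Path, name_format: str = TS_FORMAT
                     ) -> list[tuple[datetime, Path]]:
    """Timestamp-sorted (timestamp, path) pairs of the frames in a directory.

    Files whose stem does not parse as a timestamp (e.g. ``reference.png``)
    are skipped with a log message.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"frame directory {directory} does not exist")
    out = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in IMAGE_EXTS:
            continue
        try:
            out.append((parse_frame_name(p, name_format), p))
        except ValueError:
            logger.info("skipping non-timestamp image %s", p.name)
    out.sort(key=lambda tp: tp[0])
    return out


def load_frame(path: Path, view: str,
               timestamp: Optional[datetime] = None) -> Frame:
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:   # drop alpha
        pixels = pixels[:, :, :3]
    if timestamp is None:
        timestamp = parse_frame_name(Path(path))
    return Frame(pixels=pixels, timestamp=timestamp, view=view)


def iter_frames(directory: Path, view: str, name_format: str = TS_FORMAT
                ) -> Iterable[Frame]:
    """Lazily load a view's frames in time order, skipping corrupt files."""
    for ts, path in list_frame_files(directory, name_format):
        try:
            yield load_frame(path, view, ts)
        except (OSError, ValueError, RuntimeError) as exc:
            logger.warning("skipping unreadable frame %s: %s", path.name, exc)


def save_frame(frame: Frame, directory: Path,
               name_format: str = TS_FORMAT) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / frame_filename(frame.timestamp, name_format)
    iio.imwrite(path, frame.pixels)
    return path


# ---------------------------------------------------------------------------
# CSV schemas

def detections_to_df(dets: Sequence[Detection]) -> pd.DataFrame:
    rows = []
    for d in dets:
        det = d.status == "detected"
        rows.append({
            "timestamp": d.timestamp.strftime(TS_ISO),
            "view": d.view,
            "u_px": d.centroid[0] if det else np.nan,
            "v_px": d.centroid[1] if det else np.nan,
            "area_px": d.area_px if det else np.nan,
            "angle_deg": d.angle_deg if det else np.nan,
            "status": d.status,
        })
    return pd.DataFrame(rows, columns=["timestamp", "view", "u_px", "v_px",
                                       "area_px", "angle_deg", "status"])


def df_to_detections(df: pd.DataFrame) -> list[Detection]:
    out = []
    for _, r in df.iterrows():
        ts = datetime.strptime(r["timestamp"], TS_ISO)
        if r["status"] == "detected":
            out.append(Detection(timestamp=ts, view=r["view"],
                                 status="detected",
                                 centroid=(float(r["u_px"]), float(r["v_px"])),
                                 area_px=float(r["area_px"]),
                                 angle_deg=float(r["angle_deg"])))
        else:
            out.append(Detection.missing(ts, r["view"]))
    return out


def track_to_df(track: Sequence[TrackPoint3D]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"timestamp": p.timestamp.strftime(TS_ISO), "t_s": p.t_s,
          "x_mm": p.x_mm, "y_mm": p.y_mm, "z_mm": p.z_mm,
          "x_delta_mm": p.x_delta_mm, "source": p.source} for p in track],
        columns=["timestamp", "t_s", "x_mm", "y_mm", "z_mm",
                 "x_delta_mm", "source"])


def df_to_track(df: pd.DataFrame) -> list[TrackPoint3D]:
    return [TrackPoint3D(timestamp=datetime.strptime(r["timestamp"], TS_ISO),
                         t_s=float(r["t_s"]), x_mm=float(r["x_mm"]),
                         y_mm=float(r["y_mm"]), z_mm=float(r["z_mm"]),
                         x_delta_mm=float(r["x_delta_mm"]),
                         source=r["source"])
            for _, r in df.iterrows()]


def metrics_to_df(series: SpeedSeries) -> pd.DataFrame:
    cum = np.concatenate([[0.0], np.cumsum(series.speed_mm_s[1:]
                                           * np.diff(series.t_s))]) \
        if len(series.t_s) > 1 else np.zeros(len(series.t_s))
    return pd.DataFrame({"t_s": series.t_s,
                         "speed_mm_s": series.speed_mm_s,
                         "cum_dist_mm": cum})


def windows_to_df(w: WindowedSpeeds) -> pd.DataFrame:
    return pd.DataFrame({"window_index": np.arange(len(w.means)),
                         "mean_speed_mm_s": w.means})


def occupancy_to_df(grid: OccupancyGrid) -> pd.DataFrame:
    nx, ny, nz = grid.counts.shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    return pd.DataFrame({"x_bin": ix.ravel(), "y_bin": iy.ravel(),
                         "z_bin": iz.ravel(),
                         "count": grid.counts.ravel().astype(int),
                         "slice": grid.slice_label})


def write_csv(df: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f", encoding="utf-8")
    return path


class RunLog:
    """Machine-readable JSON-lines run log (stage timings, counts)."""

    def __init__(self, path: Optional[Path]):
        self.path = Path(path) if path is not None else None
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("", encoding="utf-8")

    def event(self, stage: str, **fields) -> None:
        record = {"stage": stage, "wall_time": time.time(), **fields}
        if self.path is not None:
            with self.path.open("a", encoding="utf-8") as fh:
                fh.write(json.dumps(record) + "\n")
        logger.info("%s: %s", stage, fields)
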