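"""Fuse front- and top-view detections into 3D tank coordinates.

Both cameras measure the tank's long axis (x): the front view contributes
(x, y), the top view (x, z).  After an exact inner join on capture timestamp
the two x estimates are averaged and their absolute disagreement is kept as
a per-point quality figure (``x_delta_mm``).  When either view is missing —
which for a motion-gated detector means the fish did not move — the previous
fused position is carried forward and contributes zero speed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

from .detection import Detection
from .geometry import MmPoint, PxPoint, TankGeometry, ViewCalibration, px_to_mm

logger = logging.getLogger(__name__)

#: x disagreements above this are logged as quality warnings (not rejected).
X_DELTA_WARN_MM = 50.0


class DuplicateTimestampError(ValueError):
    """One view produced two detections with the same timestamp."""


@dataclass(frozen=True)
class TrackPoint3D:
    """Per-second fused 3D position in tank millimetres."""

    timestamp: datetime
    t_s: float
    x_mm: float
    y_mm: float
    z_mm: float
    x_delta_mm: float
    source: str  # "fused" | "carried"


@dataclass
class MatchResult:
    pairs: list[tuple[datetime, Detection, Detection]]
    unmatched_front: list[datetime]
    unmatched_top: list[datetime]


def match_by_timestamp(front: Sequence[Detection],
                       top: Sequence[Detection]) -> MatchResult:
    """Inner join of the two views' detections on exact timestamp.

    Both lists must be time-sorted; a duplicated timestamp within one view is
    an error (it means two frames shared a filename-timestamp).  Timestamps
    present in only one view are reported, not silently dropped.
    """
    by_ts = {}
    for name, dets in (("front", front), ("top", top)):
        seen = set()
        for d in dets:
            if d.timestamp in seen:
                raise DuplicateTimestampError(
                    f"duplicate timestamp {d.timestamp} in {name} view")
            seen.add(d.timestamp)
        by_ts[name] = {d.timestamp: d for d in dets}
    common = sorted(by_ts["front"].keys() & by_ts["top"].keys())
    unmatched_f = sorted(by_ts["front"].keys() - by_ts["top"].keys())
    unmatched_t = sorted(by_ts["top"].keys() - by_ts["front"].keys())
    for ts in unmatched_f:
        logger.info("front frame %s has no top-view partner", ts)
    for ts in unmatched_t:
        logger.info("top frame %s has no front-view partner", ts)
    pairs = [(ts, by_ts["front"][ts], by_ts["top"][ts]) for ts in common]
    return MatchResult(pairs=pairs, unmatched_front=unmatched_f,
                       unmatched_top=unmatched_t)


def fuse_pair(pair: tuple[datetime, Detection, Detection],
              cal_front: ViewCalibration, cal_top: ViewCalibration,
              geom: TankGeometry, previous: Optional[TrackPoint3D],
              t_s: float) -> Optional[TrackPoint3D]:
    """Fuse one timestamp's pair of detections into a 3D point.

    Returns a carried copy of ``previous`` if either view is missing, or
    ``None`` when there is no previous point yet (the track starts at the
    first frame where both views detect the fish).
    """
    ts, det_f, det_t = pair
    if det_f.status != "detected" or det_t.status != "detected":
        if previous is None:
            return None
        return TrackPoint3D(timestamp=ts, t_s=t_s,
                            x_mm=previous.x_mm, y_mm=previous.y_mm,
                            z_mm=previous.z_mm, x_delta_mm=0.0,
                            source="carried")
    mf = px_to_mm(cal_front, geom, PxPoint(*det_f.centroid))
    mt = px_to_mm(cal_top, geom, PxPoint(*det_t.centroid))
    x_delta = abs(mf.x_mm - mt.x_mm)
    if x_delta > X_DELTA_WARN_MM:
        logger.warning("x disagreement %.1f mm at %s exceeds %.0f mm",
                       x_delta, ts, X_DELTA_WARN_MM)
    return TrackPoint3D(timestamp=ts, t_s=t_s,
                        x_mm=(mf.x_mm + mt.x_mm) / 2.0,
                        y_mm=mf.y_mm, z_mm=mt.z_mm,
                        x_delta_mm=x_delta, source="fused")


def fuse_tracks(match: MatchResult, cal_front: ViewCalibration,
                cal_top: ViewCalibration, geom: TankGeometry) -> list[TrackPoint3D]:
    """Fuse all matched pairs into a 3D track.

    ``t_s`` is seconds since the first matched timestamp.  Leading pairs with
    a missing view (before the first full detection) are dropped.
    """
    if not match.pairs:
        return []
    t0 = match.pairs[0][0]
    track: list[TrackPoint3D] = []
    previous: Optional[TrackPoint3D] = None
    for pair in match.pairs:
        t_s = (pair[0] - t0).total_seconds()
        pt = fuse_pair(pair, cal_front, cal_top, geom, previous, t_s)
        if pt is not None:
            track.append(pt)
            previous = pt
    return track
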