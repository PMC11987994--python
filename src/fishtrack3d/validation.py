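"""End-to-end validation harnesses over synthetic ground-truth scenes.

These functions bundle the package's standard self-checks: protocol
arithmetic (window counts for a 10-hour, 1 Hz recording), full
render→detect→fuse→measure recovery, static-scene rejection, the
Kruskal–Wallis type-I error rate, and the dose–response pattern (suppressed
locomotion at higher doses, detected by strictly decreasing recovered swim
distances and Dunn–Bonferroni flags on the high-dose pairs).

Every harness takes a seed and is fully reproducible; problem sizes default
to what a laptop CPU handles in minutes.
"""

from __future__ import annotations

from dataclasses import replace
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np

from .detection import DetectionParams, process_frame
from .fusion import TrackPoint3D, fuse_tracks, match_by_timestamp
from .geometry import TankGeometry
from .stats import (DOSE_TEMPLATE, dunn_bonferroni, kruskal_wallis,
                    synth_speed_groups)
from .synth import (GroundTruth, MotionConfig, SceneConfig, dose_profile,
                    render_views, simulate_trajectory)
from .trajectory import step_speeds, total_distance, window_means


def params_for_scene(scene: SceneConfig) -> DetectionParams:
    """Detection parameters scaled from the 640x360 defaults to a scene."""
    w, _ = scene.image_size
    scale = w / 640.0
    return DetectionParams(
        min_area_px=max(10.0, 50.0 * scale * scale),
        mask_dilate_px=max(2, int(round(5 * scale))),
        flow_downscale=2 if w >= 640 else 1,
    )


def ideal_track(gt: GroundTruth, scene: SceneConfig) -> list[TrackPoint3D]:
    """The track an error-free tracker would output for a trajectory."""
    return [TrackPoint3D(timestamp=scene.t0 + timedelta(seconds=float(t)),
                         t_s=float(t), x_mm=p[0], y_mm=p[1], z_mm=p[2],
                         x_delta_mm=0.0, source="fused")
            for t, p in zip(gt.t_s, gt.pos_mm)]


def window_count_10h(seed: int = 0, duration_s: float = 36_000.0,
                     window_s: float = 10.0) -> dict:
    """Windowed-speed count for a 10-hour, 1 frame/s recording.

    36,000 per-second speed samples reduce to exactly 3,600 ten-second
    windowed means; this is the protocol arithmetic the statistics rely on.
    """
    geom = TankGeometry()
    gt = simulate_trajectory(MotionConfig(duration_s=duration_s, seed=seed),
                             geom)
    series = step_speeds(ideal_track(gt, SceneConfig()))
    windows = window_means(series, window_s)
    return {"n_samples": len(series.speed_mm_s),
            "n_windows": len(windows.means),
            "total_distance_mm": total_distance(series)}


def run_scene(gt: GroundTruth, scene: SceneConfig, geom: TankGeometry,
              params: Optional[DetectionParams] = None) -> dict:
    """Render a trajectory and run the full pipeline over it, streaming.

    Frames are rendered and consumed one at a time so long scenes do not
    hold two full image sequences in memory.  Returns the fused track plus
    per-view detections.
    """
    params = params or params_for_scene(scene)
    cal_f, cal_t = scene.calibrations(geom)
    frames_f, frames_t, ref_f, ref_t = render_views(gt, scene, geom)
    det_f, det_t = [], []
    prev_f = prev_t = None
    for i in range(len(frames_f)):
        det_f.append(process_frame(prev_f, frames_f[i], ref_f, cal_f, params))
        det_t.append(process_frame(prev_t, frames_t[i], ref_t, cal_t, params))
        prev_f, prev_t = frames_f[i], frames_t[i]
        frames_f[i] = frames_t[i] = None   # release pixel buffers
    match = match_by_timestamp(det_f, det_t)
    track = fuse_tracks(match, cal_f, cal_t, geom)
    return {"track": track, "det_front": det_f, "det_top": det_t,
            "cal_front": cal_f, "cal_top": cal_t}


def tracking_recovery(seed: int = 0, n_frames: int = 600,
                      image_size: tuple[int, int] = (640, 360),
                      motion: Optional[MotionConfig] = None) -> dict:
    """Recovery benchmark on a noise-free two-view scene.

    Reports the detection rate (over frames whose true in-view displacement
    is at least twice the flow threshold — motion along a view's unseen axis
    is legitimately invisible to it), the mean fused 3D position error in
    pixel-equivalents, and the relative error of the recovered total
    distance against ground truth.
    """
    geom = TankGeometry()
    motion = motion or MotionConfig(duration_s=float(n_frames), seed=seed)
    scene = SceneConfig(image_size=image_size)
    if image_size != (640, 360):
        w = image_size[0] / 640.0
        scene = replace(scene, fish_semi_axes_px=(30.0 * w, 11.0 * w))
    params = params_for_scene(scene)
    gt = simulate_trajectory(motion, geom)
    res = run_scene(gt, scene, geom, params)
    cal_f, cal_t = res["cal_front"], res["cal_top"]

    rates = []
    for dets, true_px in ((res["det_front"], gt.front_px),
                          (res["det_top"], gt.top_px)):
        steps = np.linalg.norm(np.diff(true_px, axis=0), axis=1)
        eligible = [i for i in range(1, len(dets))
                    if steps[i - 1] >= 2.0 * params.mag_thresh]
        detected = sum(dets[i].status == "detected" for i in eligible)
        rates.append(detected / len(eligible) if eligible else 1.0)

    errs = []
    for pt in res["track"]:
        if pt.source != "fused":
            continue
        i = int(round(pt.t_s))
        e = np.array([(pt.x_mm - gt.pos_mm[i, 0]) * cal_f.px_per_mm_u,
                      (pt.y_mm - gt.pos_mm[i, 1]) * cal_f.px_per_mm_v,
                      (pt.z_mm - gt.pos_mm[i, 2]) * cal_t.px_per_mm_v])
        errs.append(np.linalg.norm(e))
    recovered = total_distance(step_speeds(res["track"]))
    return {
        "detection_rate": float(min(rates)),
        "mean_fused_error_px": float(np.mean(errs)),
        "recovered_distance_mm": float(recovered),
        "true_distance_mm": float(gt.total_distance_mm),
        "distance_error_pct":
            float(abs(recovered - gt.total_distance_mm)
                  / gt.total_distance_mm * 100.0),
        "n_frames": n_frames,
    }


def static_scene_detections(seed: int = 0, n_frames: int = 100,
                            image_size: tuple[int, int] = (320, 180)) -> dict:
    """Detections on a static scene (artifact present, fish immobile).

    A constant scene element — the camera's faint reflection in the glass —
    must never be detected; the expected count is zero across both views.
    """
    geom = TankGeometry()
    motion = MotionConfig(duration_s=float(n_frames), mean_speed_mm_s=0.0,
                          speed_sd=0.0, seed=seed)
    scene = SceneConfig(image_size=image_size,
                        fish_semi_axes_px=(16.0, 6.0))
    gt = simulate_trajectory(motion, geom)
    res = run_scene(gt, scene, geom)
    n_det = sum(d.status == "detected"
                for d in res["det_front"] + res["det_top"])
    return {"n_detections": n_det, "n_frames": n_frames}


def kw_type1_rate(seed: int = 0, n_groups: int = 4, n: int = 100,
                  replicates: int = 2000, alpha: float = 0.05) -> dict:
    """Kruskal–Wallis rejection rate on identically distributed groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(replicates):
        groups = [synth_speed_groups([("g", 50.0, 15.0)], n=n,
                                     seed=int(rng.integers(2 ** 31)))[0]
                  for _ in range(n_groups)]
        if kruskal_wallis(groups).p_value < alpha:
            rejections += 1
    return {"rate": rejections / replicates, "replicates": replicates}


DOSE_SUPPRESSIONS = (0.0, 0.10, 0.45, 0.75)
DOSE_AGGREGATIONS = (0.0, 0.10, 0.30, 0.60)


def dose_response_distances(seed: int = 0, duration_s: float = 180.0,
                            image_size: tuple[int, int] = (320, 180)) -> dict:
    """Recovered swim distances for four dose-analog motion profiles.

    Suppression levels mimic the inverse dose–distance relation: higher
    ammonia analog, less locomotion.  Returns recovered and true distances
    per level and whether the recovered sequence is strictly decreasing.
    """
    geom = TankGeometry()
    scene = SceneConfig(image_size=image_size, fish_semi_axes_px=(16.0, 6.0))
    base = MotionConfig(duration_s=duration_s, seed=seed)
    recovered, truth = [], []
    for level, (sup, agg) in enumerate(zip(DOSE_SUPPRESSIONS,
                                           DOSE_AGGREGATIONS)):
        motion = replace(dose_profile(base, sup, agg), seed=seed + level)
        gt = simulate_trajectory(motion, geom)
        res = run_scene(gt, scene, geom)
        recovered.append(total_distance(step_speeds(res["track"])))
        truth.append(gt.total_distance_mm)
    return {"suppressions": list(DOSE_SUPPRESSIONS),
            "recovered_mm": recovered, "true_mm": truth,
            "strictly_decreasing": bool(np.all(np.diff(recovered) < 0))}


def dose_stats_power(seed: int = 0, replicates: int = 200,
                     n: int = 3600, alpha: float = 0.05) -> dict:
    """Power of the omnibus + post hoc battery on the dose template.

    With the four-group template at n windows per group, every replicate
    should reject the omnibus and flag every pair involving the two highest
    dose analogs.
    """
    rng = np.random.default_rng(seed)
    omnibus_hits = 0
    flag_hits = 0
    for _ in range(replicates):
        groups = synth_speed_groups(DOSE_TEMPLATE, n=n,
                                    seed=int(rng.integers(2 ** 31)))
        om = kruskal_wallis(groups)
        res = dunn_bonferroni(groups, om, alpha=alpha)
        omnibus_hits += om.p_value < alpha
        idx = {lab: i for i, lab in enumerate(res.labels)}
        high_pairs_ok = all(
            res.different[idx[hi], idx[other]]
            for hi in ("200", "400")
            for other in res.labels if other != hi)
        flag_hits += high_pairs_ok
    return {"omnibus_rate": omnibus_hits / replicates,
            "high_dose_flag_rate": flag_hits / replicates,
            "replicates": replicates, "n_per_group": n}
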