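"""Run configuration: paths, geometry, calibration and pipeline parameters.

A run is described by a YAML (or JSON) mapping; every key has a default, so
a minimal config only points at the frame directories::

    front_dir: run1/front
    top_dir: run1/top
    out_dir: run1/out
    tank: {width_mm: 540, depth_mm: 370, height_mm: 400, water_mm: 200}
    front: {roi: [0, 0, 640, 360]}       # v_flip defaults to true for front
    top: {roi: [0, 0, 640, 360]}
    detection: {mag_thresh: 1.0, min_area_px: 50}
    window_s: 10
    alpha: 0.05
    seed: 0

References default to ``<view_dir>/reference.png``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .detection import DetectionParams
from .geometry import FRONT, TOP, ConfigError, TankGeometry, ViewCalibration
from .io import TS_FORMAT


@dataclass
class RunConfig:
    front_dir: Path = Path("front")
    top_dir: Path = Path("top")
    out_dir: Path = Path("out")
    front_reference: Optional[Path] = None     # default: front_dir/reference.png
    top_reference: Optional[Path] = None
    geom: TankGeometry = field(default_factory=TankGeometry)
    cal_front: Optional[ViewCalibration] = None
    cal_top: Optional[ViewCalibration] = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    window_s: float = 10.0
    alpha: float = 0.05
    seed: int = 0
    name_format: str = TS_FORMAT

    def __post_init__(self) -> None:
        self.front_dir = Path(self.front_dir)
        self.top_dir = Path(self.top_dir)
        self.out_dir = Path(self.out_dir)
        if self.front_reference is None:
            self.front_reference = self.front_dir / "reference.png"
        if self.top_reference is None:
            self.top_reference = self.top_dir / "reference.png"

    def calibration(self, view: str) -> ViewCalibration:
        cal = self.cal_front if view == FRONT else self.cal_top
        if cal is None:
            raise ConfigError(
                f"no calibration for view {view!r}; set its roi in the config "
                "or build one with ViewCalibration.for_tank")
        return cal

    @classmethod
    def from_mapping(cls, data: dict, base_dir: Optional[Path] = None) -> "RunConfig":
        base = Path(base_dir) if base_dir is not None else Path(".")

        def _path(key: str, default=None):
            if key in data:
                return base / data[key]
            return default

        geom = TankGeometry(**data.get("tank", {}))
        cfg = cls(
            front_dir=_path("front_dir", base / "front"),
            top_dir=_path("top_dir", base / "top"),
            out_dir=_path("out_dir", base / "out"),
            front_reference=_path("front_reference"),
            top_reference=_path("top_reference"),
            geom=geom,
            detection=DetectionParams(**data.get("detection", {})),
            window_s=float(data.get("window_s", 10.0)),
            alpha=float(data.get("alpha", 0.05)),
            seed=int(data.get("seed", 0)),
            name_format=data.get("name_format", TS_FORMAT),
        )
        for view, attr in ((FRONT, "cal_front"), (TOP, "cal_top")):
            block = data.get(view)
            if block is not None:
                roi = tuple(block["roi"])
                setattr(cfg, attr, ViewCalibration.for_tank(
                    view, roi, geom, v_flip=block.get("v_flip")))
        return cfg

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must contain a mapping")
        return cls.from_mapping(data, base_dir=path.parent)
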