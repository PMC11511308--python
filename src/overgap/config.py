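"""Run configuration: one YAML-serialisable object driving every stage.

All randomness in a run flows from the single ``seed``; two runs with equal
configurations are bit-identical.  ``parse(write(config)) == config`` holds
(collections are normalised to tuples on load).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .geometry import CameraSpec, FovKind, acquisition_spacing, image_extent
from .synthetic import ScenarioSpec

__all__ = [
    "DetectionConfig",
    "CorrectionConfig",
    "IoConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class DetectionConfig:
    rois: tuple[tuple[int, int], ...] = ()  # row bands [start, end); empty = full frame
    tol: int = 0
    search_halfwidth: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rois", tuple((int(a), int(b)) for a, b in self.rois)
        )


@dataclass(frozen=True)
class CorrectionConfig:
    n_bound: int = 20  # vertical rescale search bound N, pixels
    w_d: Optional[int] = None  # desired tile width; None = first frame width

    def __post_init__(self) -> None:
        if self.n_bound < 0:
            raise ValueError("n_bound must be >= 0")
        if self.w_d is not None and self.w_d < 1:
            raise ValueError("w_d must be >= 1")


@dataclass(frozen=True)
class IoConfig:
    frames_dir: str = "frames"
    positions_csv: str = "positions.csv"
    out_dir: str = "out"


@dataclass(frozen=True)
class RunConfig:
    camera: Optional[CameraSpec] = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    io: IoConfig = field(default_factory=IoConfig)
    spacing_m: Optional[float] = None  # explicit trigger spacing override
    seed: int = 0

    def effective_spacing_m(self) -> float:
        """Trigger spacing: explicit override, else IW/2 from the camera,
        else the simulator's own pixel schedule converted to metres."""
        if self.spacing_m is not None:
            return self.spacing_m
        if self.camera is not None:
            return acquisition_spacing(image_extent(self.camera))
        return (self.scenario.frame_w - 1) / 2.0 / self.scenario.px_per_m


def _camera_to_dict(cam: CameraSpec) -> dict:
    return {
        "res_w": cam.res_w,
        "res_h": cam.res_h,
        "fov_kind": cam.fov_kind.value,
        "fov_deg": cam.fov_deg,
        "distance_m": cam.distance_m,
    }


def to_dict(cfg: RunConfig) -> dict:
    sc = cfg.scenario
    return {
        "camera": None if cfg.camera is None else _camera_to_dict(cfg.camera),
        "detection": {
            "rois": [list(r) for r in cfg.detection.rois],
            "tol": cfg.detection.tol,
            "search_halfwidth": cfg.detection.search_halfwidth,
        },
        "correction": {"n_bound": cfg.correction.n_bound, "w_d": cfg.correction.w_d},
        "scenario": {
            "scene_w": sc.scene_w,
            "scene_h": sc.scene_h,
            "frame_w": sc.frame_w,
            "n_triples": sc.n_triples,
            "anomalies": [list(a) for a in sc.anomalies],
            "scale_offsets": [list(s) for s in sc.scale_offsets],
            "noise_sd": sc.noise_sd,
            "seed": sc.seed,
            "px_per_m": sc.px_per_m,
            "texture_sigma": sc.texture_sigma,
        },
        "io": {
            "frames_dir": cfg.io.frames_dir,
            "positions_csv": cfg.io.positions_csv,
            "out_dir": cfg.io.out_dir,
        },
        "spacing_m": cfg.spacing_m,
        "seed": cfg.seed,
    }


def from_dict(d: dict) -> RunConfig:
    cam = d.get("camera")
    camera = None
    if cam is not None:
        camera = CameraSpec(
            res_w=int(cam["res_w"]),
            res_h=int(cam["res_h"]),
            fov_kind=FovKind(str(cam["fov_kind"]).lower()),
            fov_deg=float(cam["fov_deg"]),
            distance_m=float(cam["distance_m"]),
        )
    det = d.get("detection", {}) or {}
    cor = d.get("correction", {}) or {}
    sc = d.get("scenario", {}) or {}
    io = d.get("io", {}) or {}
    return RunConfig(
        camera=camera,
        detection=DetectionConfig(
            rois=tuple(tuple(r) for r in det.get("rois", ())),
            tol=int(det.get("tol", 0)),
            search_halfwidth=det.get("search_halfwidth"),
        ),
        correction=CorrectionConfig(
            n_bound=int(cor.get("n_bound", 20)), w_d=cor.get("w_d")
        ),
        scenario=ScenarioSpec(
            scene_w=int(sc.get("scene_w", 2000)),
            scene_h=int(sc.get("scene_h", 283)),
            frame_w=int(sc.get("frame_w", 360)),
            n_triples=int(sc.get("n_triples", 3)),
            anomalies=tuple(tuple(a) for a in sc.get("anomalies", ())),
            scale_offsets=tuple(tuple(s) for s in sc.get("scale_offsets", ())),
            noise_sd=float(sc.get("noise_sd", 0.0)),
            seed=int(sc.get("seed", 0)),
            px_per_m=float(sc.get("px_per_m", 270.0)),
            texture_sigma=float(sc.get("texture_sigma", 3.0)),
        ),
        io=IoConfig(
            frames_dir=str(io.get("frames_dir", "frames")),
            positions_csv=str(io.get("positions_csv", "positions.csv")),
            out_dir=str(io.get("out_dir", "out")),
        ),
        spacing_m=d.get("spacing_m"),
        seed=int(d.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)
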