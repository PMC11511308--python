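"""Reading frame sequences and writing run outputs.

Images are PNG/TIFF, 8- or 16-bit, gray or RGB; intensities are normalised
to ``[0, 1]`` on load and colour frames additionally get a derived gray
channel using Rec.601 luma weights (0.299, 0.587, 0.114) — the single stated
convention for gray conversion.  Positions arrive as a CSV with columns
``frame_id, position_m``; rows may be in any order, frames are sorted by
position.  Column indices in reports are 0-based; positions are metres with
a ``.`` decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .detection import Frame, Role
from .errors import InvalidInputError
from .pipeline import TripleRecord
from .synthetic import GroundTruth, ScenarioSpec, render_scene, simulate_frames

__all__ = [
    "REC601_WEIGHTS",
    "to_gray",
    "read_frames",
    "write_outputs",
    "write_scenario",
]

REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _normalise(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Rec.601 luma of an ``H x W x 3`` image in ``[0, 1]``."""
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise InvalidInputError("expected an H x W x 3 image")
    return rgb[..., :3] @ REC601_WEIGHTS


def read_frames(
    images, positions_csv
) -> tuple[list[Frame], list[Optional[np.ndarray]]]:
    """Load an ordered frame sequence with positions.

    ``images`` is a directory (all PNG/TIFF files in it) or an explicit list
    of paths; ``positions_csv`` must map each image's filename stem
    (``frame_id``) to its along-track ``position_m``.  Frames are ordered by
    position and assigned alternating main/secondary roles.  Returns the
    grayscale frames plus, per frame, the colour array when the source was
    RGB (``None`` for gray sources).
    """
    images = Path(images) if isinstance(images, (str, Path)) else images
    if isinstance(images, Path):
        if not images.is_dir():
            raise InvalidInputError(f"{images} is not a directory")
        paths = sorted(
            p for p in images.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
    else:
        paths = [Path(p) for p in images]
    if not paths:
        raise InvalidInputError("no input images found")

    table = pd.read_csv(positions_csv)
    required = {"frame_id", "position_m"}
    if not required.issubset(table.columns):
        raise InvalidInputError(
            f"position log must have columns {sorted(required)}, got "
            f"{list(table.columns)}"
        )
    positions = dict(zip(table["frame_id"].astype(str), table["position_m"].astype(float)))
    missing = [p.stem for p in paths if p.stem not in positions]
    if missing:
        raise InvalidInputError(f"no position for frames: {missing}")

    paths = sorted(paths, key=lambda p: positions[p.stem])
    frames: list[Frame] = []
    rgb_out: list[Optional[np.ndarray]] = []
    for i, path in enumerate(paths):
        arr = _normalise(iio.imread(path))
        if arr.ndim == 3:
            rgb = arr[..., :3]
            gray = to_gray(rgb)
            rgb_out.append(rgb)
        else:
            gray = arr
            rgb_out.append(None)
        frames.append(
            Frame(
                pixels=np.clip(gray, 0.0, 1.0),
                position_m=positions[path.stem],
                role=Role.MAIN if i % 2 == 0 else Role.SECONDARY,
            )
        )
    return frames, rgb_out


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def write_outputs(
    tiles: Sequence[np.ndarray],
    log: Sequence[TripleRecord],
    out_dir,
    config_dict: Optional[dict] = None,
    seed: Optional[int] = None,
) -> None:
    """Write tiles, the per-triple report and a run log.

    Tiles become zero-padded numbered 8-bit PNGs; the report is a CSV with
    one row per completed triple (0-based column indices); the run log
    echoes the configuration and seed for reproducibility.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, tile in enumerate(tiles):
        iio.imwrite(out / f"tile_{i:04d}.png", _to_uint8(np.asarray(tile)))
    report = pd.DataFrame(
        [
            {
                "triple_id": r.triple_index,
                "q1": r.q1,
                "q2": r.q2,
                "kind": r.kind.value,
                "n1": r.n1,
                "n2": r.n2,
                "d1": r.d1,
                "d2": r.d2,
                "emitted": r.emitted,
                "flags": ";".join(r.flags),
            }
            for r in log
        ],
        columns=[
            "triple_id", "q1", "q2", "kind", "n1", "n2", "d1", "d2", "emitted", "flags",
        ],
    )
    report.to_csv(out / "report.csv", index=False)
    run_log = {
        "seed": seed,
        "n_tiles": len(tiles),
        "n_triples": len(log),
        "conventions": "column indices 0-based; positions in metres",
        "config": config_dict,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)


def write_scenario(out_dir, spec: ScenarioSpec) -> GroundTruth:
    """Render a scenario to disk: frame PNGs, position CSV, truth JSON.

    The fixture set produced here is exactly what :func:`read_frames`
    expects back, so a simulate-then-run round trip exercises the full I/O
    path.
    """
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    scene = render_scene(spec)
    frames, positions, truth = simulate_frames(scene, spec)
    rows = []
    for i, frame in enumerate(frames):
        name = f"frame_{i:04d}"
        iio.imwrite(frames_dir / f"{name}.png", _to_uint8(frame.pixels))
        rows.append({"frame_id": name, "position_m": frame.position_m})
    pd.DataFrame(rows).to_csv(out / "positions.csv", index=False)
    iio.imwrite(out / "scene.png", _to_uint8(scene))
    payload = {
        "starts": list(truth.starts),
        "triples": [
            {"q1": t.q1, "q2": t.q2, "kind": t.kind.value, "width": t.width}
            for t in truth.triples
        ],
        "scale_offsets": list(truth.scale_offsets),
        "spacing_m": truth.spacing_m,
        "mosaic_w": truth.mosaic_w,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return truth
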