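"""Synthetic acquisition simulator with exact ground truth.

The simulator renders a wide, seeded, textured scene (smoothed noise plus
gradients and sparse shapes — a stand-in for the strip/canopy imagery the
detector is designed for, with pairwise-distinct columns) and "photographs"
it with a sliding window, producing the alternating main/secondary frame
sequence of a position-triggered acquisition.

Discrete schedule.  In a perfect acquisition, consecutive *main* frames
share exactly one boundary column — the junction column appears as the last
column of one and the first column of the next — so the main-to-main step is
``frame_w - 1`` scene columns and the secondary frame sits halfway at
``(frame_w - 1) // 2``.  With this convention the detector's no-anomaly
condition is exactly ``q1 == q2``.  An injected overlap of width ``k``
shifts the next main window back by ``k`` columns (ground truth
``q1 - q2 = k``; ``k + 1`` duplicated columns counting both junction
endpoints); a gap shifts it forward (``q2 - q1 = k``; ``k - 1`` scene
columns are seen only by the secondary frame).  Shifts accumulate: later
frames continue from the displaced position.

Distance changes are emulated by vertically rescaling a frame's content with
the same resize primitive the corrector uses, which makes inversion recovery
well-posed; this is a deliberate simplification of a true perspective
change.  Gaussian intensity noise is added last and clipped to ``[0, 1]``.

Reported camera positions follow the *nominal* trigger schedule (uniform
``IW/2`` steps converted to metres through ``px_per_m``), decoupled from the
anomalous pixel windows — as with a GPS-triggered camera, the measured
progress, not the true scene coverage, drives acquisition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .correction import rescale_image_height
from .detection import AnomalyKind, Frame, Role
from .errors import DimensionMismatchError, ScenarioError

__all__ = [
    "ScenarioSpec",
    "TripleTruth",
    "GroundTruth",
    "ReconstructionScore",
    "render_scene",
    "simulate_frames",
    "score_reconstruction",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulated acquisition run.

    ``anomalies`` is an ordered list of ``(triple_index, kind, width)``
    with ``kind`` in {"overlap", "gap"}; ``scale_offsets`` maps frame index
    to a signed vertical rescale in pixels.  Defaults mirror the scale of
    the reference examples this simulator emulates: a 2000 px-wide scene of
    283 px-tall frames captured 360 px wide.
    """

    scene_w: int = 2000
    scene_h: int = 283
    frame_w: int = 360
    n_triples: int = 3
    anomalies: tuple[tuple[int, str, int], ...] = ()
    scale_offsets: tuple[tuple[int, int], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    px_per_m: float = 270.0
    texture_sigma: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "anomalies", tuple((int(t), str(k), int(w)) for t, k, w in self.anomalies)
        )
        object.__setattr__(
            self, "scale_offsets", tuple((int(i), int(m)) for i, m in self.scale_offsets)
        )
        if self.frame_w > self.scene_w:
            raise ScenarioError("frame_w must not exceed scene_w")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be >= 0")
        if self.n_triples < 1:
            raise ScenarioError("need at least one triple")
        for t, kind, width in self.anomalies:
            if kind not in ("overlap", "gap"):
                raise ScenarioError(f"unknown anomaly kind {kind!r}")
            if not 0 <= t < self.n_triples:
                raise ScenarioError(f"anomaly triple index {t} out of range")
            if not 1 <= width < self.frame_w // 2:
                raise ScenarioError(
                    "anomaly width must be in [1, frame_w/2) so the secondary "
                    "frame contains it"
                )

    @property
    def n_frames(self) -> int:
        return 2 * self.n_triples + 1

    def offset_of(self, frame_index: int) -> int:
        return dict(self.scale_offsets).get(frame_index, 0)


@dataclass(frozen=True)
class TripleTruth:
    """Exact detector answer for one simulated triple."""

    q1: int
    q2: int
    kind: AnomalyKind
    width: int  # injected shift (0 when no anomaly)


@dataclass(frozen=True)
class GroundTruth:
    """Everything a scorer needs: the scene, the schedule and the answers."""

    scene: np.ndarray
    starts: tuple[int, ...]  # true scene column of each frame's leading edge
    triples: tuple[TripleTruth, ...]
    scale_offsets: tuple[int, ...]  # per frame, in acquisition order
    spacing_m: float
    mosaic_w: int  # scene columns covered by the corrected mosaic, from 0

    def tile_window(self, tile_index: int, w_d: int) -> np.ndarray:
        """Scene window the ``tile_index``-th emitted tile should reproduce."""
        lo = tile_index * w_d
        return self.scene[:, lo : lo + w_d]


def render_scene(spec: ScenarioSpec) -> np.ndarray:
    """Deterministic textured scene in ``[0, 1]`` with distinct columns.

    Smoothed Gaussian noise provides continuous texture (making duplicate
    columns a measure-zero event), a gentle two-axis gradient breaks
    large-scale symmetry, and sparse bright/dark rectangles and ellipses add
    the object-like structure that anchors histogram comparisons.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.scene_h, spec.scene_w
    img = gaussian_filter(rng.standard_normal((h, w)), spec.texture_sigma)
    yy, xx = np.mgrid[0:h, 0:w]
    img = img / (np.abs(img).max() + 1e-12)
    img += 0.3 * (xx / max(w - 1, 1)) + 0.2 * (yy / max(h - 1, 1))
    n_shapes = max(8, w // 60)
    for _ in range(n_shapes):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        ry = int(rng.integers(max(2, h // 20), max(3, h // 5)))
        rx = int(rng.integers(max(2, w // 200), max(3, w // 30)))
        amp = float(rng.uniform(-0.8, 0.8))
        if rng.random() < 0.5:
            mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        else:
            mask = (np.abs(yy - cy) <= ry) & (np.abs(xx - cx) <= rx)
        img = img + amp * mask
    img = gaussian_filter(img, 1.0)
    img -= img.min()
    img /= img.max() + 1e-12
    return 0.02 + 0.96 * img  # keep a margin inside [0, 1] for additive noise


def simulate_frames(
    scene: np.ndarray, spec: ScenarioSpec
) -> tuple[list[Frame], np.ndarray, GroundTruth]:
    """Capture the frame sequence over ``scene`` per the scenario schedule.

    Returns the frames (alternating main/secondary roles), the nominal
    camera positions in metres, and the exact ground truth.
    """
    scene = np.asarray(scene, dtype=np.float64)
    w = spec.frame_w
    half = (w - 1) // 2
    anomalies = {t: (kind, width) for t, kind, width in spec.anomalies}

    starts: list[int] = [0]
    truths: list[TripleTruth] = []
    left = 0
    for t in range(spec.n_triples):
        s2 = left + half
        kind_s, width = anomalies.get(t, ("none", 0))
        delta = {"overlap": -width, "gap": width, "none": 0}[kind_s]
        s3 = left + (w - 1) + delta
        q1 = (left + w - 1) - s2
        q2 = s3 - s2
        truths.append(
            TripleTruth(q1=q1, q2=q2, kind=AnomalyKind(kind_s if width else "none"), width=width)
        )
        starts.extend([s2, s3])
        left = s3
    if left + w > scene.shape[1] or min(starts) < 0:
        raise ScenarioError(
            f"schedule needs scene columns [0, {left + w}) but scene is "
            f"{scene.shape[1]} wide"
        )

    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    frames: list[Frame] = []
    offsets: list[int] = []
    spacing_px = (w - 1) / 2.0
    positions = np.arange(spec.n_frames) * spacing_px / spec.px_per_m
    for i, s in enumerate(starts):
        window = scene[:, s : s + w]
        m = spec.offset_of(i)
        offsets.append(m)
        if m != 0:
            window = rescale_image_height(window, m)
        if spec.noise_sd > 0:
            window = window + noise_rng.normal(0.0, spec.noise_sd, window.shape)
            window = np.clip(window, 0.0, 1.0)
        frames.append(
            Frame(
                pixels=window,
                position_m=float(positions[i]),
                role=Role.MAIN if i % 2 == 0 else Role.SECONDARY,
            )
        )
    truth = GroundTruth(
        scene=scene,
        starts=tuple(starts),
        triples=tuple(truths),
        scale_offsets=tuple(offsets),
        spacing_m=float(spacing_px / spec.px_per_m),
        mosaic_w=left + w,
    )
    return frames, positions, truth


@dataclass(frozen=True)
class ReconstructionScore:
    """Per-tile mean absolute error vs the scene, plus detection confusion."""

    tile_mae: tuple[float, ...]
    confusion: dict = field(default_factory=dict)  # (truth kind, detected kind) -> count

    @property
    def max_mae(self) -> float:
        return max(self.tile_mae) if self.tile_mae else 0.0


def score_reconstruction(
    tiles: Sequence[np.ndarray],
    truth: GroundTruth,
    detected_kinds: Optional[Sequence[AnomalyKind]] = None,
) -> ReconstructionScore:
    """Compare emitted tiles against their ground-truth scene windows.

    Tiles are consecutive fixed-width windows of the corrected scene stream
    starting at column 0.  When the per-triple detected kinds are supplied,
    a (truth, detected) confusion count is included.
    """
    maes = []
    for i, tile in enumerate(tiles):
        tile = np.asarray(tile, dtype=np.float64)
        window = truth.tile_window(i, tile.shape[1])
        if window.shape != tile.shape:
            raise DimensionMismatchError(
                f"tile {i} of shape {tile.shape} vs scene window {window.shape}"
            )
        maes.append(float(np.mean(np.abs(tile - window))))
    confusion: Counter = Counter()
    if detected_kinds is not None:
        for t, detected in zip(truth.triples, detected_kinds):
            confusion[(t.kind, AnomalyKind(detected))] += 1
    return ReconstructionScore(tile_mae=tuple(maes), confusion=dict(confusion))
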