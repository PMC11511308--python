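"""The real-time acquisition/correction loop.

Frames are captured every ``IW/2`` metres of along-track travel and
alternate roles: odd arrivals are main images (MI) — the output sequence —
and even arrivals are secondary images (SI), used only to localise and
correct the anomaly between the two MIs flanking them.  Each time a triple
(left MI, SI, right MI) completes, the anomaly is detected and corrected,
tiles of the desired width ``W_d`` are emitted, and the undersized remainder
is carried over as the next left MI; a remainder wider than ``W_d`` emits
several tiles at once.  Unrecoverable anomalies (wider than the frame) pass
through uncorrected with a flag rather than aborting the run.

The loop is throughput-bound, not latency-bound: with trigger spacing ``S``
metres and a per-triple processing time ``T`` seconds, the platform keeps up
in real time as long as its speed stays below ``S/T`` m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .correction import (
    CorrectionResult,
    correct_gap,
    correct_overlap,
    merge_plain,
)
from .detection import (
    AnomalyKind,
    AnomalyReport,
    Frame,
    Role,
    RoiSpec,
    locate_q1_q2,
    multi_roi_consensus,
)
from .errors import InvalidInputError, MonotonicityError, UnrecoverableAnomalyError

__all__ = [
    "PipelineState",
    "TripleRecord",
    "SpeedBound",
    "should_acquire",
    "step",
    "run",
    "max_speed",
]

# Tolerance absorbing float round-off in position differences so that a
# stream spaced exactly IW/2 apart always triggers.
_POS_EPS = 1e-9


@dataclass(frozen=True)
class SpeedBound:
    """Real-time speed limit ``v_max = S/T`` for spacing ``S`` and time ``T``."""

    spacing_m: float
    triple_time_s: float
    v_max: float


def max_speed(spacing_m: float, triple_time_s: float) -> SpeedBound:
    """Maximum platform speed (m/s) that keeps the loop real-time."""
    if spacing_m <= 0 or triple_time_s <= 0:
        raise InvalidInputError("spacing and processing time must be positive")
    return SpeedBound(spacing_m, triple_time_s, spacing_m / triple_time_s)


def should_acquire(prev_pos_m: float, cur_pos_m: float, spacing_m: float) -> bool:
    """True iff the platform has travelled at least ``spacing_m`` since the
    last trigger (inclusive, with a 1e-9 m float-safety margin)."""
    if cur_pos_m < prev_pos_m:
        raise MonotonicityError(
            f"position regressed from {prev_pos_m} to {cur_pos_m}"
        )
    return cur_pos_m - prev_pos_m >= spacing_m - _POS_EPS


@dataclass(frozen=True)
class TripleRecord:
    """Per-triple log entry: what was detected and what was applied."""

    triple_index: int
    q1: int
    q2: int
    kind: AnomalyKind
    d1: float
    d2: float
    n1: Optional[int]
    n2: Optional[int]
    emitted: int
    flags: tuple[str, ...] = ()


@dataclass
class PipelineState:
    """Rolling state of the acquisition loop."""

    spacing_m: float
    w_d: Optional[int] = None
    n_bound: int = 20
    tol: int = 0
    roi: Union[RoiSpec, Sequence[RoiSpec], None] = None
    last_trigger_pos_m: float = -math.inf
    frame_index: int = 0
    held_left: Optional[Frame] = None
    held_si: Optional[Frame] = None
    emitted: int = 0
    log: list = field(default_factory=list)

    @property
    def triples_done(self) -> int:
        return len(self.log)


def _detect(state: PipelineState, left: Frame, si: Frame, right: Frame) -> AnomalyReport:
    roi = state.roi
    if roi is None or isinstance(roi, RoiSpec):
        return locate_q1_q2(left, si, right, roi, state.tol)
    reports = [locate_q1_q2(left, si, right, r, state.tol) for r in roi]
    return multi_roi_consensus(reports, state.tol)


def _process_triple(
    state: PipelineState, left: Frame, si: Frame, right: Frame
) -> tuple[list[np.ndarray], Frame]:
    report = _detect(state, left, si, right)
    flags: tuple[str, ...] = ()
    try:
        if report.kind is AnomalyKind.OVERLAP:
            result = correct_overlap(left, si, right, report, state.w_d, state.n_bound)
        elif report.kind is AnomalyKind.GAP:
            result = correct_gap(left, si, right, report, state.w_d, state.n_bound)
        else:
            result = merge_plain(left, si, right, report, state.w_d)
        flags = result.flags
    except UnrecoverableAnomalyError:
        # Field robustness: pass the pair through uncorrected, flagged.
        merged = np.hstack([left.pixels, right.pixels])
        tile = merged[:, : state.w_d] if merged.shape[1] >= state.w_d else None
        remainder = merged[:, state.w_d :] if tile is not None else merged
        result = CorrectionResult(tile, remainder, report, (), ("uncorrected",))
        flags = result.flags

    # Cut the merged stream into tiles; a wide remainder emits several.  The
    # final cut is held back when it would leave fewer than two carry-over
    # columns — the next left MI needs a junction column to match against —
    # so such a tile is simply emitted one round later.
    merged = result.merged
    tiles: list[np.ndarray] = []
    while merged.shape[1] - state.w_d >= 2:
        tiles.append(merged[:, : state.w_d].copy())
        merged = merged[:, state.w_d :]
    remainder = merged
    ns = [r.n_star for r in result.rescales]
    state.log.append(
        TripleRecord(
            triple_index=state.triples_done,
            q1=report.q1,
            q2=report.q2,
            kind=report.kind,
            d1=report.d1,
            d2=report.d2,
            n1=ns[0] if len(ns) > 0 else None,
            n2=ns[1] if len(ns) > 1 else None,
            emitted=len(tiles),
            flags=flags,
        )
    )
    new_left = Frame(pixels=remainder, position_m=right.position_m, role=Role.MAIN)
    return tiles, new_left


def step(state: PipelineState, frame: Frame) -> tuple[PipelineState, list[np.ndarray]]:
    """Feed one acquired frame; return emitted tiles (usually none or one).

    Roles follow arrival parity: the first frame (and every corrected
    remainder) is a main image, the next a secondary image, and the frame
    completing a triple triggers detection and correction.  The remainder
    inherits the main role, restarting parity relative to it.
    """
    state.frame_index += 1
    if state.w_d is None:
        state.w_d = frame.width
    if state.held_left is None:
        state.held_left = frame
        return state, []
    if state.held_si is None:
        state.held_si = frame
        return state, []
    tiles, new_left = _process_triple(state, state.held_left, state.held_si, frame)
    state.held_left = new_left
    state.held_si = None
    state.emitted += len(tiles)
    return state, tiles


def run(
    stream: Iterable[tuple[float, Frame]],
    spacing_m: float,
    w_d: Optional[int] = None,
    n_bound: int = 20,
    tol: int = 0,
    roi: Union[RoiSpec, Sequence[RoiSpec], None] = None,
) -> tuple[list[np.ndarray], list[TripleRecord], PipelineState]:
    """Run the full loop over an aligned ``(position_m, frame)`` stream.

    The position trigger subsamples the stream (acquisitions end up at least
    ``spacing_m`` apart); each acquired frame is fed to :func:`step`.
    Returns the emitted tiles, the per-triple log and the final state.
    """
    if spacing_m <= 0:
        raise InvalidInputError("spacing_m must be positive")
    state = PipelineState(
        spacing_m=spacing_m, w_d=w_d, n_bound=n_bound, tol=tol, roi=roi
    )
    tiles: list[np.ndarray] = []
    for pos, frame in stream:
        if not should_acquire(state.last_trigger_pos_m, pos, spacing_m):
            continue
        state.last_trigger_pos_m = pos
        state, emitted = step(state, frame)
        tiles.extend(emitted)
    return tiles, state.log, state
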