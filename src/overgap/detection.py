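"""Anomaly detection: locate q1/q2 in a secondary frame and classify.

Frames arrive as an alternating sequence of main images (MI) and secondary
images (SI); the detector works on one triple (left MI, SI, right MI) at a
time.  Two column matches are performed with DTW:

* ``q1`` — the SI column most similar to the *last* column of the left MI,
* ``q2`` — the SI column most similar to the *first* column of the right MI.

In a perfectly scheduled acquisition the two boundary columns image the same
scene column, so ``q1 == q2``.  ``q1 - q2 > tol`` means the main frames share
duplicated scene content (overlap anomaly, the SI columns ``q2..q1`` being
the overlapping portion); ``q2 - q1 > tol`` means scene content between them
was missed (gap anomaly, recoverable from the SI columns strictly between
``q1`` and ``q2``).

Matching may be restricted to a horizontal band of rows (an ROI, e.g. a
drawing-strip at the base of a plant row, or a low-leaf region); corrections
are always applied to full frames.  Several ROIs can be combined by
averaging their reports.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DimensionMismatchError, InvalidInputError
from .metrics import dtw_many

__all__ = [
    "Role",
    "AnomalyKind",
    "Frame",
    "RoiSpec",
    "AnomalyReport",
    "classify",
    "match_column",
    "locate_q1_q2",
    "multi_roi_consensus",
]


class Role(str, enum.Enum):
    MAIN = "main"
    SECONDARY = "secondary"


class AnomalyKind(str, enum.Enum):
    OVERLAP = "overlap"
    GAP = "gap"
    NONE = "none"


@dataclass(frozen=True)
class Frame:
    """One acquired image.

    ``pixels`` is an ``H x W`` intensity matrix in ``[0, 1]`` with row 0 at
    the top and column 0 at the trailing (earlier-acquired) edge, so the
    column index increases along the travel direction.  ``position_m`` is the
    scalar along-track camera position at capture time.
    """

    pixels: np.ndarray
    position_m: float
    role: Role = Role.MAIN

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise InvalidInputError("frame must be a 2-D image of at least 2x2 pixels")
        if float(px.min()) < 0.0 or float(px.max()) > 1.0:
            raise InvalidInputError("frame intensities must lie in [0, 1]")
        if not isinstance(self.role, Role):
            object.__setattr__(self, "role", Role(str(self.role).lower()))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class RoiSpec:
    """Half-open row interval ``[row_start, row_end)`` used for matching."""

    row_start: int
    row_end: int

    def __post_init__(self) -> None:
        if not 0 <= self.row_start < self.row_end:
            raise InvalidInputError("need 0 <= row_start < row_end")

    def rows(self, frame: Frame) -> np.ndarray:
        if self.row_end > frame.height:
            raise DimensionMismatchError(
                f"ROI rows [{self.row_start}, {self.row_end}) exceed frame height "
                f"{frame.height}"
            )
        return frame.pixels[self.row_start : self.row_end]


@dataclass(frozen=True)
class AnomalyReport:
    """Result of matching one triple.

    ``q1``/``q2`` are SI column indices (0-based), ``d1``/``d2`` the minimised
    DTW costs at those columns.  ``border_warning`` is set when a match lands
    on an SI border column: the geometric guarantee that the anomaly is fully
    contained in the SI may then be violated.
    """

    q1: int
    q2: int
    kind: AnomalyKind
    d1: float
    d2: float
    border_warning: bool = False

    @property
    def overlap_width(self) -> int:
        """Number of duplicated SI columns ``q2..q1`` (overlap triples only)."""
        return self.q1 - self.q2 + 1

    @property
    def gap_width(self) -> int:
        """Number of missing scene columns, i.e. SI columns strictly between
        ``q1`` and ``q2`` (gap triples only)."""
        return self.q2 - self.q1 - 1


def classify(q1: int, q2: int, tol: int = 0) -> AnomalyKind:
    """Overlap iff ``q1 - q2 > tol``; gap iff ``q2 - q1 > tol``; else none."""
    if q1 - q2 > tol:
        return AnomalyKind.OVERLAP
    if q2 - q1 > tol:
        return AnomalyKind.GAP
    return AnomalyKind.NONE


def _band(frame: Frame, roi: Optional[RoiSpec]) -> np.ndarray:
    return frame.pixels if roi is None else roi.rows(frame)


def match_column(
    ref,
    image: Frame,
    roi: Optional[RoiSpec] = None,
    search: Optional[tuple[int, int]] = None,
) -> tuple[int, float]:
    """Index (and DTW cost) of the image column most similar to ``ref``.

    The argmin is taken over all columns of ``image`` restricted to the ROI
    rows; ties break toward the smallest index.  ``search`` optionally
    restricts the scan to a half-open column interval (an optimisation around
    the expected junction); the returned index is always in full-image
    coordinates.
    """
    ref = np.asarray(ref, dtype=np.float64).ravel()
    band = _band(image, roi)
    if ref.size != band.shape[0]:
        raise DimensionMismatchError(
            f"reference column height {ref.size} != ROI height {band.shape[0]}"
        )
    lo, hi = 0, band.shape[1]
    if search is not None:
        lo = max(int(search[0]), 0)
        hi = min(int(search[1]), band.shape[1])
        if lo >= hi:
            raise InvalidInputError("empty search window")
    dists = dtw_many(ref, band[:, lo:hi])
    j = int(np.argmin(dists))  # np.argmin returns the first minimum: smallest index
    return lo + j, float(dists[j])


def locate_q1_q2(
    mi_left: Frame,
    si: Frame,
    mi_right: Frame,
    roi: Optional[RoiSpec] = None,
    tol: int = 0,
    search_halfwidth: Optional[int] = None,
) -> AnomalyReport:
    """Match both MI boundary columns into the SI and classify the triple.

    ``search_halfwidth``, if given, limits each scan to a window of that many
    columns around the expected junction (the SI centre column); by default
    the whole SI is scanned.
    """
    search = None
    if search_halfwidth is not None:
        c = si.width // 2
        search = (c - search_halfwidth, c + search_halfwidth + 1)
    ref1 = _band(mi_left, roi)[:, -1]
    ref2 = _band(mi_right, roi)[:, 0]
    q1, d1 = match_column(ref1, si, roi, search)
    q2, d2 = match_column(ref2, si, roi, search)
    border = q1 in (0, si.width - 1) or q2 in (0, si.width - 1)
    return AnomalyReport(
        q1=q1, q2=q2, kind=classify(q1, q2, tol), d1=d1, d2=d2, border_warning=border
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def multi_roi_consensus(
    reports: Sequence[AnomalyReport], tol: int = 0
) -> AnomalyReport:
    """Average several per-ROI reports of the same triple into one.

    ``q1`` and ``q2`` are the arithmetic means rounded half-up; the anomaly
    kind is recomputed from the averaged indices.  DTW costs are averaged and
    the border warning is the disjunction.
    """
    if len(reports) == 0:
        raise InvalidInputError("need at least one report")
    if len(reports) == 1:
        return replace(reports[0], kind=classify(reports[0].q1, reports[0].q2, tol))
    q1 = _round_half_up(float(np.mean([r.q1 for r in reports])))
    q2 = _round_half_up(float(np.mean([r.q2 for r in reports])))
    return AnomalyReport(
        q1=q1,
        q2=q2,
        kind=classify(q1, q2, tol),
        d1=float(np.mean([r.d1 for r in reports])),
        d2=float(np.mean([r.d2 for r in reports])),
        border_warning=any(r.border_warning for r in reports),
    )
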