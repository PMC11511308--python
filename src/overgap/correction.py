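"""Anomaly correction: vertical rescaling, overlap removal, gap filling.

A change in camera-to-scene distance between two captures shows up as a
vertical rescale of the frame content.  The corrector searches, over integer
offsets ``n`` in ``[-N, N]``, for the rescale of a probe column that brings
its intensity histogram closest (in 1-D Wasserstein distance) to the
histogram of a reference column known to image the same scene region at the
correct scale; the whole frame is then resized by the winning offset before
columns are removed (overlap) or inserted (gap).

Rescaling a column by ``n`` means linear interpolation to ``H + n`` samples
followed by a centre-symmetric crop (``n > 0``) or edge-value pad (``n < 0``)
back to the original height ``H``, so frame heights are invariant.

Geometric bookkeeping uses the junction convention of the detector: SI
columns ``q2..q1`` are duplicated in an overlap (both endpoints included),
so ``q1 - q2 + 1`` columns are dropped from the left edge of the rescaled
right frame; in a gap, SI columns ``q1..q2-1`` form the gap portion, which
is rescaled against the left frame's last column and then loses its first
column (the duplicate of that very reference) before insertion.  The left
main image is never modified.  All geometric decisions are recorded in the
returned :class:`CorrectionResult` so they can be replayed verbatim on the
R, G and B channels of a colour frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .detection import AnomalyKind, AnomalyReport, Frame
from .errors import (
    DimensionMismatchError,
    InvalidInputError,
    InvalidScaleError,
    MisuseError,
    UnrecoverableAnomalyError,
)
from .metrics import column_histogram, fd_bin_edges, wasserstein_1d

__all__ = [
    "RescaleResult",
    "CorrectionResult",
    "rescale_column",
    "rescale_image_height",
    "best_rescale",
    "correct_overlap",
    "correct_gap",
    "merge_plain",
    "apply_to_color",
]

ImageLike = Union[Frame, np.ndarray]


def _pixels(img: ImageLike) -> np.ndarray:
    if isinstance(img, Frame):
        return img.pixels
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError("expected a 2-D image")
    return arr


@dataclass(frozen=True)
class RescaleResult:
    """Outcome of the Wasserstein search over vertical offsets.

    ``n_star`` is the offset in ``[-N, N]`` minimising the distance between
    the reference histogram and the histogram of the rescaled probe column;
    ties break toward the smallest ``|n|``, negative before positive (least
    intervention first).  ``wd_curve[i]`` is the distance at offset
    ``i - N``.
    """

    n_star: int
    wd_min: float
    wd_curve: np.ndarray

    @property
    def n_bound(self) -> int:
        return (len(self.wd_curve) - 1) // 2


@dataclass(frozen=True)
class CorrectionResult:
    """One corrected triple: the emitted tile (if any) and the carry-over.

    ``tile`` has exactly the desired width when present; ``remainder`` is the
    leftover corrected image that becomes the next left main image.
    ``rescales`` lists the vertical rescale searches applied, in order
    (overlap: one; gap: gap portion then right frame; none: empty).
    """

    tile: Optional[np.ndarray]
    remainder: np.ndarray
    report: AnomalyReport
    rescales: tuple[RescaleResult, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def merged(self) -> np.ndarray:
        parts = [self.remainder] if self.tile is None else [self.tile, self.remainder]
        return np.hstack(parts)


def rescale_column(col, n: int):
    """Rescale a column by ``n`` signed pixels, preserving its length.

    The column is linearly interpolated to ``H + n`` samples; for ``n > 0``
    the result is centre-cropped back to ``H``, for ``n < 0`` it is padded
    symmetrically with its nearest computed end values.  ``n = 0`` returns a
    copy.
    """
    v = np.asarray(col, dtype=np.float64).ravel()
    h = v.size
    n = int(n)
    if h + n < 2:
        raise InvalidScaleError(f"rescale by {n} leaves fewer than 2 of {h} pixels")
    if n == 0:
        return v.copy()
    out = np.interp(np.linspace(0.0, h - 1.0, h + n), np.arange(h), v)
    if n > 0:
        top = n // 2
        return out[top : top + h]
    pad_top = (-n) // 2
    pad_bot = -n - pad_top
    return np.concatenate(
        [np.full(pad_top, out[0]), out, np.full(pad_bot, out[-1])]
    )


def rescale_image_height(img: ImageLike, n: int) -> np.ndarray:
    """Apply :func:`rescale_column` with the same ``n`` to every column."""
    px = _pixels(img)
    n = int(n)
    if n == 0:
        return px.copy()
    return np.column_stack([rescale_column(px[:, j], n) for j in range(px.shape[1])])


def best_rescale(ref, target, n_bound: int) -> RescaleResult:
    """Find the vertical offset making ``target`` photometrically match ``ref``.

    For every ``n`` in ``[-n_bound, n_bound]`` the probe column is rescaled by
    ``n`` and its histogram — on bin edges derived from the *reference*
    column, so the per-``n`` curve is comparable — is compared to the
    reference histogram by 1-D Wasserstein distance.
    """
    ref = np.asarray(ref, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if ref.size != target.size:
        raise DimensionMismatchError("ref and target columns must share a height")
    if n_bound < 0:
        raise InvalidInputError("n_bound must be >= 0")
    edges = fd_bin_edges(ref)
    h_ref = column_histogram(ref, edges)
    offsets = np.arange(-n_bound, n_bound + 1)
    curve = np.array(
        [
            wasserstein_1d(h_ref, column_histogram(rescale_column(target, n), edges))
            for n in offsets
        ]
    )
    # argmin with ties broken by smallest |n|, then negative before positive
    best = min(range(offsets.size), key=lambda i: (curve[i], abs(int(offsets[i])), int(offsets[i])))
    return RescaleResult(
        n_star=int(offsets[best]), wd_min=float(curve[best]), wd_curve=curve
    )


def _cut(merged: np.ndarray, w_d: int) -> tuple[Optional[np.ndarray], np.ndarray]:
    if w_d < 1:
        raise InvalidInputError("desired tile width must be >= 1")
    if merged.shape[1] >= w_d:
        return merged[:, :w_d].copy(), merged[:, w_d:].copy()
    return None, merged.copy()


def _check_heights(*imgs: np.ndarray) -> None:
    heights = {img.shape[0] for img in imgs}
    if len(heights) != 1:
        raise DimensionMismatchError(f"frames must share a height, got {heights}")


def _merge_overlap(left, si, right, q1, q2, n):
    op_width = q1 - q2 + 1
    if op_width >= right.shape[1]:
        raise UnrecoverableAnomalyError(
            f"overlap of {op_width} columns is as wide as the right frame"
        )
    right_rs = rescale_image_height(right, n)
    return np.hstack([left, right_rs[:, op_width:]])


def _merge_gap(left, si, right, q1, q2, n1, n2):
    gp = si[:, q1:q2]
    gp_rs = rescale_image_height(gp, n1) if gp.shape[1] else gp
    n_gp = gp_rs[:, 1:]
    right_rs = rescale_image_height(right, n2)
    return np.hstack([left, n_gp, right_rs])


def _merge_none(left, si, right, q1, q2):
    # Even an anomaly-free triple shares the junction column between the two
    # main frames (q1 == q2 images the same scene column in both), so a plain
    # concatenation would duplicate it; drop the duplicated prefix instead.
    if q1 >= q2:
        drop = q1 - q2 + 1
        if drop >= right.shape[1]:
            raise UnrecoverableAnomalyError("junction overlap spans the right frame")
        return np.hstack([left, right[:, drop:]])
    return np.hstack([left, si[:, q1 + 1 : q2], right])


def correct_overlap(
    mi_left: ImageLike,
    si: ImageLike,
    mi_right: ImageLike,
    report: AnomalyReport,
    w_d: int,
    n_bound: int = 20,
) -> CorrectionResult:
    """Remove the overlapping portion and emit a tile of the desired width.

    The right frame is first resized vertically by the offset that best maps
    its junction column (the duplicate of the left frame's last column) onto
    that reference — the left frame is never modified — then its
    ``q1 - q2 + 1`` duplicated leading columns are dropped; the
    concatenation is cut at ``w_d``.
    """
    if report.kind is not AnomalyKind.OVERLAP:
        raise MisuseError(f"correct_overlap called on a {report.kind.value} report")
    left, mid, right = _pixels(mi_left), _pixels(si), _pixels(mi_right)
    _check_heights(left, mid, right)
    op_width = report.overlap_width
    if op_width >= right.shape[1]:
        raise UnrecoverableAnomalyError(
            f"overlap of {op_width} columns is as wide as the right frame"
        )
    # Probe with the junction column: right-frame column q1 - q2 images the
    # same scene column as the left frame's last column, so the search
    # compares two views of identical content and is exactly zero-offset in
    # the undistorted case.
    probe = right[:, op_width - 1]
    res = best_rescale(left[:, -1], probe, n_bound)
    merged = _merge_overlap(left, mid, right, report.q1, report.q2, res.n_star)
    tile, remainder = _cut(merged, w_d)
    flags = ("border_warning",) if report.border_warning else ()
    return CorrectionResult(tile, remainder, report, (res,), flags)


def correct_gap(
    mi_left: ImageLike,
    si: ImageLike,
    mi_right: ImageLike,
    report: AnomalyReport,
    w_d: int,
    n_bound: int = 20,
) -> CorrectionResult:
    """Fill the gap portion from the secondary frame and emit a tile.

    Two vertical corrections are made: the gap portion (SI columns
    ``q1..q2-1``) is rescaled toward the left frame's last column and loses
    its first column (the duplicate of that reference); then the right frame
    is rescaled toward the corrected-scale view of its own junction column
    (SI column ``q2``).  The three pieces are concatenated and cut at
    ``w_d``.
    """
    if report.kind is not AnomalyKind.GAP:
        raise MisuseError(f"correct_gap called on a {report.kind.value} report")
    left, mid, right = _pixels(mi_left), _pixels(si), _pixels(mi_right)
    _check_heights(left, mid, right)
    flags = []
    if report.border_warning or report.q2 >= mid.shape[1] - 1:
        # The gap portion touches the SI border: scene content may be missing
        # beyond what the SI can supply.  Correct what is recoverable.
        flags.append("unrecoverable_border")
    res1 = best_rescale(left[:, -1], mid[:, report.q1], n_bound)
    gp = mid[:, report.q1 : report.q2]
    gp_rs = rescale_image_height(gp, res1.n_star) if gp.shape[1] else gp
    n_gp = gp_rs[:, 1:]
    # Reference for the right frame: SI column q2 brought to the corrected
    # scale — it images the same scene column as the right frame's first
    # column, mirroring how the gap portion itself was referenced against
    # the left frame's duplicate (SI column q1).
    ref2 = rescale_column(mid[:, report.q2], res1.n_star)
    res2 = best_rescale(ref2, right[:, 0], n_bound)
    merged = np.hstack([left, n_gp, rescale_image_height(right, res2.n_star)])
    tile, remainder = _cut(merged, w_d)
    return CorrectionResult(tile, remainder, report, (res1, res2), tuple(flags))


def merge_plain(
    mi_left: ImageLike,
    si: ImageLike,
    mi_right: ImageLike,
    report: AnomalyReport,
    w_d: int,
) -> CorrectionResult:
    """Merge an anomaly-free triple (no vertical rescale) and cut at ``w_d``."""
    left, mid, right = _pixels(mi_left), _pixels(si), _pixels(mi_right)
    _check_heights(left, mid, right)
    merged = _merge_none(left, mid, right, report.q1, report.q2)
    tile, remainder = _cut(merged, w_d)
    return CorrectionResult(tile, remainder, report, ())


def _replay_channel(
    result: CorrectionResult, left, si, right
) -> np.ndarray:
    r = result.report
    kind = r.kind
    if kind is AnomalyKind.OVERLAP:
        return _merge_overlap(left, si, right, r.q1, r.q2, result.rescales[0].n_star)
    if kind is AnomalyKind.GAP:
        gp = si[:, r.q1 : r.q2]
        gp_rs = (
            rescale_image_height(gp, result.rescales[0].n_star)
            if gp.shape[1]
            else gp
        )
        n_gp = gp_rs[:, 1:]
        right_rs = rescale_image_height(right, result.rescales[1].n_star)
        return np.hstack([left, n_gp, right_rs])
    return _merge_none(left, si, right, r.q1, r.q2)


def apply_to_color(
    result: CorrectionResult,
    mi_left_rgb: np.ndarray,
    si_rgb: np.ndarray,
    mi_right_rgb: np.ndarray,
) -> tuple[Optional[np.ndarray], np.ndarray]:
    """Replay a correction's geometry on each channel of an ``H x W x C`` triple.

    The anomaly decision (``q1``, ``q2``, kind, rescale offsets, cut
    position) was computed once on the grayscale frames; here the identical
    crop/fill/rescale/cut is applied independently per channel, so the
    corrected colour tile is consistent with the corrected gray tile.
    Returns ``(tile, remainder)`` with the channel axis preserved (``tile``
    is ``None`` when the merge is narrower than the tile width).
    """
    imgs = [np.asarray(a, dtype=np.float64) for a in (mi_left_rgb, si_rgb, mi_right_rgb)]
    if any(a.ndim != 3 for a in imgs):
        raise DimensionMismatchError("expected H x W x C colour images")
    channels = {a.shape[2] for a in imgs}
    if len(channels) != 1:
        raise DimensionMismatchError(f"channel counts differ: {channels}")
    w_d = result.remainder.shape[1] if result.tile is None else result.tile.shape[1]
    merged = np.stack(
        [
            _replay_channel(result, imgs[0][..., c], imgs[1][..., c], imgs[2][..., c])
            for c in range(imgs[0].shape[2])
        ],
        axis=-1,
    )
    if result.tile is None:
        return None, merged
    return merged[:, :w_d].copy(), merged[:, w_d:].copy()
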