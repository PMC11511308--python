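"""The two distances the anomaly detector/corrector relies on.

Dynamic time warping (DTW) between image columns localises, inside a
secondary frame, the column most similar to a boundary column of a main
frame; because DTW allows monotone local stretching it stays informative when
the two frames were captured at slightly different camera-to-scene distances.
The first-order Wasserstein distance between column intensity histograms
(binned by the Freedman–Diaconis rule) measures how far apart two columns are
*photometrically* regardless of pixel alignment, and drives the search for
the vertical rescale offset that undoes a distance change.

Conventions (stated once, here, for reproducibility):

* DTW uses absolute-difference local cost, the classic {match, insert,
  delete} step pattern, no global band and no path-length normalisation.
  Only the argmin over candidate columns is consumed downstream, so
  normalisation would at most perturb near-ties.
* Freedman–Diaconis bin width ``h = 2 IQR n**(-1/3)`` with the IQR taken
  from linear-interpolation (type-7) quantiles; bin count ``ceil(range/h)``;
  equal-width edges spanning ``[min, max]``.  Degenerate inputs (constant
  column, a single sample, zero IQR) fall back instead of raising.
* The 1-D Wasserstein distance between two histograms on *identical* edges
  is the CDF-difference sum ``sum_k |P_k - Q_k| * width_k``, which for point
  masses at bin centres reduces to the distance between the centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import IncompatibleBinningError, InvalidBinningError, InvalidInputError

__all__ = [
    "BinnedDistribution",
    "dtw_distance",
    "dtw_many",
    "fd_bin_edges",
    "column_histogram",
    "wasserstein_1d",
]

# Half-width of the fallback bin used for constant columns.
_CONSTANT_EPS = 1e-6


@njit(cache=False)
def _dtw_kernel(a, b):  # pragma: no cover - exercised through dtw_distance
    n = a.shape[0]
    m = b.shape[0]
    prev = np.empty(m + 1, dtype=np.float64)
    cur = np.empty(m + 1, dtype=np.float64)
    for j in range(m + 1):
        prev[j] = np.inf
    prev[0] = 0.0
    for i in range(n):
        cur[0] = np.inf
        ai = a[i]
        for j in range(m):
            c = ai - b[j]
            if c < 0.0:
                c = -c
            best = prev[j]
            if prev[j + 1] < best:
                best = prev[j + 1]
            if cur[j] < best:
                best = cur[j]
            cur[j + 1] = c + best
        tmp = prev
        prev = cur
        cur = tmp
    return prev[m]


@njit(cache=False)
def _dtw_many_kernel(ref, cols):  # pragma: no cover
    w = cols.shape[1]
    out = np.empty(w, dtype=np.float64)
    for j in range(w):
        out[j] = _dtw_kernel(ref, cols[:, j])
    return out


def _as_column(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise InvalidInputError(f"{name} must be non-empty")
    return arr


def dtw_distance(a, b) -> float:
    """Unnormalised DTW cost between two intensity columns.

    Dynamic programming over the full alignment grid with local cost
    ``|a_i - b_j|`` and steps {match, insert, delete}; symmetric in its
    arguments.  Zero iff one column is a monotone duplication of the other.
    """
    av = _as_column(a, "a")
    bv = _as_column(b, "b")
    return float(_dtw_kernel(av, bv))


def dtw_many(ref, columns) -> np.ndarray:
    """DTW cost of ``ref`` against every column of an ``H x W`` matrix.

    Equivalent to ``[dtw_distance(ref, columns[:, j]) for j in range(W)]``
    but runs entirely in compiled code; this is the hot loop of column
    matching.
    """
    rv = _as_column(ref, "ref")
    cols = np.asarray(columns, dtype=np.float64)
    if cols.ndim != 2 or cols.shape[0] == 0 or cols.shape[1] == 0:
        raise InvalidInputError("columns must be a non-empty 2-D array")
    return _dtw_many_kernel(rv, np.asfortranarray(cols))


def fd_bin_edges(values) -> np.ndarray:
    """Equal-width histogram edges for a column via the Freedman–Diaconis rule.

    Returns an array of at least two strictly increasing edges.  Degenerate
    inputs never raise: a constant column (or a single sample) yields one bin
    of width ``2e-6`` centred on the value, and a zero IQR with non-zero range
    yields a single bin spanning ``[min, max]``.
    """
    v = _as_column(values, "values")
    lo = float(v.min())
    hi = float(v.max())
    if v.size == 1 or hi == lo:
        c = lo
        return np.array([c - _CONSTANT_EPS, c + _CONSTANT_EPS])
    q25, q75 = np.percentile(v, [25.0, 75.0])  # linear interpolation = type 7
    iqr = float(q75 - q25)
    if iqr <= 0.0:
        return np.array([lo, hi])
    h = 2.0 * iqr * v.size ** (-1.0 / 3.0)
    k = int(np.ceil((hi - lo) / h))
    return np.linspace(lo, hi, max(k, 1) + 1)


@dataclass(frozen=True)
class BinnedDistribution:
    """A histogram normalised to a probability distribution.

    ``edges`` are strictly increasing bin boundaries (intensity units) and
    ``probs`` the per-bin probabilities (``len(probs) == len(edges) - 1``,
    non-negative, summing to one).
    """

    edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.float64)
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "probs", probs)
        if edges.ndim != 1 or edges.size < 2:
            raise InvalidBinningError("need at least two bin edges")
        if np.any(np.diff(edges) <= 0):
            raise InvalidBinningError("bin edges must be strictly increasing")
        if probs.shape != (edges.size - 1,):
            raise InvalidBinningError("probs must have one entry per bin")
        if np.any(probs < 0) or abs(float(probs.sum()) - 1.0) > 1e-9:
            raise InvalidBinningError("probs must be non-negative and sum to 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def column_histogram(values, edges) -> BinnedDistribution:
    """Histogram of a column on the given edges, normalised to probabilities.

    Values outside the edge range are clipped into the end bins, so a
    candidate column may safely be binned on edges derived from a different
    (reference) column.
    """
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2:
        raise InvalidBinningError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise InvalidBinningError("bin edges must be strictly increasing")
    v = _as_column(values, "values")
    clipped = np.clip(v, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return BinnedDistribution(edges=edges, probs=counts / counts.sum())


def wasserstein_1d(p: BinnedDistribution, q: BinnedDistribution) -> float:
    """First-order Wasserstein distance between histograms on shared edges.

    Each bin's mass sits at its centre, and the distance is the integral of
    the absolute CDF difference over the centre grid:
    ``sum_k |CDF_p(k) - CDF_q(k)| * (c_{k+1} - c_k)``.  This is the exact
    optimal-transport cost between the two centre-supported distributions
    (two point masses at centres c1, c2 cost ``|c1 - c2|``); for equal-width
    bins the centre spacing equals the bin width.  Requires ``p`` and ``q``
    to share identical bin edges.
    """
    if p.edges.size != q.edges.size or not np.allclose(
        p.edges, q.edges, rtol=0.0, atol=1e-12
    ):
        raise IncompatibleBinningError("distributions must share identical bin edges")
    cdf_diff = np.cumsum(p.probs - q.probs)[:-1]
    return float(np.sum(np.abs(cdf_diff) * np.diff(p.centers)))
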