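"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: DTW is
checked against exhaustive warping-path enumeration and a plain-Python
dynamic program, quantiles against the standard library, and optimal
transport against scipy's sort-based solver.
"""

from __future__ import annotations

import numpy as np
import pytest

import overgap as og


# ---------------------------------------------------------------------------
# independent oracles


def dtw_brute_force(a, b) -> float:
    """Minimum path cost over *all* monotone warping paths, by enumeration.

    Steps are (down, right, diagonal) on the alignment grid from (0, 0) to
    (n-1, m-1); admissible pruning (costs are non-negative) keeps the search
    exhaustive over optimal candidates while staying fast for length <= 6.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n, m = len(a), len(b)
    best = [float("inf")]

    def walk(i: int, j: int, acc: float) -> None:
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def dtw_plain_python(a, b) -> float:
    """Textbook O(nm) DTW dynamic program in pure Python."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    inf = float("inf")
    prev = [inf] * (len(b) + 1)
    prev[0] = 0.0
    for ai in a:
        cur = [inf]
        for j, bj in enumerate(b):
            cur.append(abs(ai - bj) + min(prev[j], prev[j + 1], cur[j]))
        prev = cur
    return prev[-1]


def strip_column(rng: np.random.Generator, height: int = 283) -> np.ndarray:
    """A smooth monotone intensity profile, like a printed gradient band.

    Random span, curvature (power warp) and direction; this is the kind of
    edge-anchored smooth content the drawing-strip scenario provides and the
    vertical-rescale search is designed for.
    """
    y = np.linspace(0.0, 1.0, height)
    a = rng.uniform(0.3, 3.0)
    lo, hi = sorted(rng.uniform(0.0, 1.0, 2))
    while hi - lo < 0.3:
        lo, hi = sorted(rng.uniform(0.0, 1.0, 2))
    col = lo + (hi - lo) * y**a
    if rng.random() < 0.5:
        col = col[::-1].copy()
    return col


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_run():
    """Factory for small, fast simulated runs (80 px frames, 60 px tall)."""

    def make(
        anomalies=(),
        scale_offsets=(),
        seed=0,
        n_triples=2,
        noise_sd=0.0,
        frame_w=80,
        scene_h=60,
    ):
        shifts = sum(w if k == "gap" else 0 for _, k, w in anomalies)
        scene_w = (frame_w - 1) * n_triples + frame_w + shifts + 8
        spec = og.ScenarioSpec(
            scene_w=scene_w,
            scene_h=scene_h,
            frame_w=frame_w,
            n_triples=n_triples,
            anomalies=tuple(anomalies),
            scale_offsets=tuple(scale_offsets),
            noise_sd=noise_sd,
            seed=seed,
        )
        scene = og.render_scene(spec)
        frames, positions, truth = og.simulate_frames(scene, spec)
        return scene, frames, positions, truth

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(20240914)
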