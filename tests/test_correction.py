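"""Vertical rescaling and overlap/gap correction against scene ground truth."""

import numpy as np
import pytest
from scipy.interpolate import interp1d

import overgap as og
from overgap.io import to_gray
from overgap.errors import (
    InvalidScaleError,
    MisuseError,
    UnrecoverableAnomalyError,
)
from .conftest import strip_column


def interp_crop_pad_oracle(col, n):
    """Independent resize oracle: scipy linear interpolation, then a
    centre-symmetric crop (n > 0) or nearest-value pad (n < 0)."""
    col = np.asarray(col, dtype=float)
    h = len(col)
    f = interp1d(np.arange(h), col, kind="linear")
    out = f(np.linspace(0.0, h - 1.0, h + n))
    if n > 0:
        top = n // 2
        return out[top : top + h]
    if n < 0:
        pad_top = (-n) // 2
        return np.concatenate(
            [np.repeat(out[0], pad_top), out, np.repeat(out[-1], -n - pad_top)]
        )
    return out


class TestRescaleColumn:
    def test_zero_offset_is_identity(self, rng):
        col = rng.random(40)
        assert np.array_equal(og.rescale_column(col, 0), col)

    @pytest.mark.parametrize("n", [-10, -3, -1, 0, 1, 3, 10])
    def test_length_is_preserved_for_all_offsets(self, rng, n):
        assert len(og.rescale_column(rng.random(40), n)) == 40

    @pytest.mark.parametrize("n", [4, 7, -4, -7])
    def test_matches_independent_interpolation_oracle(self, n):
        ramp = np.linspace(0.0, 1.0, 40)
        out = og.rescale_column(ramp, n)
        assert np.allclose(out, interp_crop_pad_oracle(ramp, n), atol=1e-6)

    def test_textured_column_matches_oracle(self, rng):
        col = rng.random(55)
        for n in (-9, 5):
            assert np.allclose(
                og.rescale_column(col, n), interp_crop_pad_oracle(col, n), atol=1e-10
            )

    def test_too_strong_shrink_raises(self):
        with pytest.raises(InvalidScaleError):
            og.rescale_column([0.1, 0.2, 0.3], -2)


class TestRescaleImage:
    def test_zero_offset_is_identity_and_height_preserved(self, rng):
        img = rng.random((30, 8))
        assert np.array_equal(og.rescale_image_height(img, 0), img)
        for n in (-6, 6):
            assert og.rescale_image_height(img, n).shape == (30, 8)

    def test_every_column_equals_columnwise_rescale(self, rng):
        img = rng.random((25, 6))
        for n in (-5, 3):
            out = og.rescale_image_height(img, n)
            for j in range(6):
                assert np.array_equal(out[:, j], og.rescale_column(img[:, j], n))


class TestBestRescale:
    def test_identical_columns_prefer_zero_offset(self, rng):
        col = rng.random(80)
        res = og.best_rescale(col, col, 10)
        assert res.n_star == 0
        assert res.wd_min == 0.0

    def test_offset_stays_inside_the_search_bound(self, rng):
        for _ in range(5):
            res = og.best_rescale(rng.random(60), rng.random(60), 7)
            assert -7 <= res.n_star <= 7
            assert res.wd_min == res.wd_curve.min()

    def test_recovers_moderate_inverse_offsets_on_smooth_gradients(self):
        """Shrinking/stretching a smooth monotone profile by a moderate m is
        undone to within the search's resolution: mostly within one pixel of
        +m, never more than a few (the histogram distance resolves offsets
        up to a small composition bias and its 1/H mass quantisation; see
        the methods note)."""
        rng = np.random.default_rng(7)
        errors = []
        for _ in range(100):
            ref = strip_column(rng)
            m = int(rng.integers(-12, 13))
            res = og.best_rescale(ref, og.rescale_column(ref, -m), 20)
            errors.append(abs(res.n_star - m))
        assert max(errors) <= 3
        assert np.mean(np.asarray(errors) <= 1) >= 0.85


class TestCorrectOverlap:
    def test_noiseless_overlap_reconstructs_the_scene_exactly(self, small_run):
        scene, frames, _, truth = small_run(anomalies=[(0, "overlap", 13)], n_triples=1)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        result = og.correct_overlap(frames[0], frames[1], frames[2], report, 80, 10)
        assert result.tile.shape[1] == 80
        mosaic = np.hstack([result.tile, result.remainder])
        assert np.array_equal(mosaic, scene[:, : mosaic.shape[1]])
        assert result.rescales[0].n_star == 0

    def test_removed_mass_equals_duplicated_secondary_region(self, small_run):
        """The overlapping portion dropped from the right frame carries the
        same total intensity as the duplicated SI region q2..q1."""
        _, frames, _, _ = small_run(anomalies=[(0, "overlap", 9)], n_triples=1)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        removed = frames[2].pixels[:, : report.q1 - report.q2 + 1]
        si_region = frames[1].pixels[:, report.q2 : report.q1 + 1]
        assert np.isclose(removed.sum(), si_region.sum())

    def test_distance_change_is_recovered_and_corrected(self):
        """Overlap triple of 360 x 283 frames with asymmetric distance
        changes (secondary stretched +10 px, right frame shrunk -25 px);
        the corrected mosaic stays close to the true scene."""
        spec = og.ScenarioSpec(
            scene_w=740, scene_h=283, frame_w=360, n_triples=1,
            anomalies=((0, "overlap", 60),), scale_offsets=((1, 10), (2, -25)), seed=5,
        )
        scene = og.render_scene(spec)
        frames, _, truth = og.simulate_frames(scene, spec)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        assert report.kind is og.AnomalyKind.OVERLAP
        result = og.correct_overlap(frames[0], frames[1], frames[2], report, 360, 30)
        mosaic = np.hstack([result.tile, result.remainder])
        mae = np.mean(np.abs(mosaic - scene[:, : mosaic.shape[1]]))
        assert mae <= 0.02
        assert result.rescales[0].n_star > 15  # undoes most of the -25 shrink

    def test_wrong_kind_raises(self, small_run):
        _, frames, _, _ = small_run(anomalies=[(0, "gap", 5)], n_triples=1)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        with pytest.raises(MisuseError):
            og.correct_overlap(frames[0], frames[1], frames[2], report, 80, 10)

    def test_overlap_spanning_the_right_frame_is_unrecoverable(self, rng):
        report = og.AnomalyReport(q1=11, q2=2, kind=og.AnomalyKind.OVERLAP, d1=0, d2=0)
        imgs = [rng.random((12, 10)) for _ in range(3)]
        with pytest.raises(UnrecoverableAnomalyError):
            og.correct_overlap(*imgs, report, 10, 5)


class TestCorrectGap:
    def test_noiseless_gap_is_filled_from_the_secondary_frame(self, small_run):
        scene, frames, _, _ = small_run(anomalies=[(0, "gap", 12)], n_triples=1)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        result = og.correct_gap(frames[0], frames[1], frames[2], report, 80, 10)
        mosaic = np.hstack([result.tile, result.remainder])
        assert np.array_equal(mosaic, scene[:, : mosaic.shape[1]])

    def test_width_bookkeeping_before_the_cut(self, small_run):
        _, frames, _, _ = small_run(anomalies=[(0, "gap", 12)], n_triples=1)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        result = og.correct_gap(frames[0], frames[1], frames[2], report, 80, 10)
        total = result.tile.shape[1] + result.remainder.shape[1]
        expected = (
            frames[0].width + (report.q2 - report.q1 - 1) + frames[2].width
        )
        assert total == expected

    def test_gap_with_distance_changes_is_corrected(self):
        """Gap triple of 320 x 283 frames with the secondary shrunk -25 px
        and the right frame stretched +10 px."""
        spec = og.ScenarioSpec(
            scene_w=740, scene_h=283, frame_w=320, n_triples=1,
            anomalies=((0, "gap", 50),), scale_offsets=((1, -25), (2, 10)), seed=6,
        )
        scene = og.render_scene(spec)
        frames, _, _ = og.simulate_frames(scene, spec)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        assert report.kind is og.AnomalyKind.GAP
        result = og.correct_gap(frames[0], frames[1], frames[2], report, 320, 30)
        mosaic = np.hstack([result.tile, result.remainder])
        mae = np.mean(np.abs(mosaic - scene[:, : mosaic.shape[1]]))
        assert mae <= 0.02

    def test_minimal_shift_gap_concatenates_exactly(self, small_run):
        """A forward shift of one column leaves no missing content: the gap
        portion is empty and the frames abut exactly."""
        scene, frames, _, _ = small_run(anomalies=[(0, "gap", 1)], n_triples=1)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        assert report.gap_width == 0
        result = og.correct_gap(frames[0], frames[1], frames[2], report, 80, 10)
        mosaic = np.hstack([result.tile, result.remainder])
        assert np.array_equal(mosaic, scene[:, : mosaic.shape[1]])

    def test_wrong_kind_raises(self, small_run):
        _, frames, _, _ = small_run(anomalies=[(0, "overlap", 5)], n_triples=1)
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        with pytest.raises(MisuseError):
            og.correct_gap(frames[0], frames[1], frames[2], report, 80, 10)


class TestColorReplay:
    def make_rgb_triple(self, small_run, anomalies):
        scene, frames, _, _ = small_run(anomalies=anomalies, n_triples=1)
        rng = np.random.default_rng(99)
        rgbs = []
        for f in frames[:3]:
            # channels: correlated variations of the gray content
            r = np.clip(f.pixels * 1.0, 0, 1)
            g = np.clip(f.pixels * 0.8 + 0.1, 0, 1)
            b = np.clip(1.0 - f.pixels * 0.6, 0, 1)
            rgbs.append(np.stack([r, g, b], axis=-1))
        return frames, rgbs

    def test_gray_of_corrected_color_equals_corrected_gray(self, small_run):
        frames, rgbs = self.make_rgb_triple(small_run, [(0, "overlap", 9)])
        grays = [to_gray(a) for a in rgbs]
        report = og.locate_q1_q2(
            og.Frame(grays[0], 0.0), og.Frame(grays[1], 1.0), og.Frame(grays[2], 2.0)
        )
        result = og.correct_overlap(grays[0], grays[1], grays[2], report, 80, 10)
        tile_rgb, rem_rgb = og.apply_to_color(result, *rgbs)
        assert tile_rgb.shape[2] == 3
        assert np.allclose(to_gray(tile_rgb), result.tile, atol=1e-9)
        assert np.allclose(to_gray(rem_rgb), result.remainder, atol=1e-9)

    def test_anomaly_free_triple_leaves_channel_values_untouched(self, small_run):
        frames, rgbs = self.make_rgb_triple(small_run, [])
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        assert report.kind is og.AnomalyKind.NONE
        result = og.merge_plain(frames[0], frames[1], frames[2], report, 80)
        tile_rgb, rem_rgb = og.apply_to_color(result, *rgbs)
        # pure re-arrangement: the emitted pixels are copies, not resamples
        drop = report.q1 - report.q2 + 1
        expected = np.concatenate([rgbs[0], rgbs[2][:, drop:]], axis=1)
        assert np.array_equal(np.concatenate([tile_rgb, rem_rgb], axis=1), expected)

    def test_channel_count_mismatch_raises(self, small_run):
        frames, rgbs = self.make_rgb_triple(small_run, [(0, "overlap", 9)])
        report = og.locate_q1_q2(frames[0], frames[1], frames[2])
        result = og.correct_overlap(frames[0], frames[1], frames[2], report, 80, 10)
        bad = rgbs[1][..., :2]
        with pytest.raises(og.errors.DimensionMismatchError):
            og.apply_to_color(result, rgbs[0], bad, rgbs[2])
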