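import numpy as np
import pytest

from icgfa import (
    CurveFormatError,
    PerfusionCurve,
    ROILine,
    VideoFormatError,
    VideoStack,
    extract_pixel_curves,
    extract_roi_curves,
    read_curves,
    read_video,
    stabilize,
    write_curves,
    write_video,
)


def textured_frame(rng, shape=(48, 64)):
    return (rng.random(shape) * 200).astype(np.uint8)


class TestVideoStack:
    def test_duration_follows_frame_count(self):
        v = VideoStack(np.zeros((7200, 8, 8), dtype=np.uint8), frame_rate=30.0)
        assert v.duration_s == pytest.approx(240.0)

    def test_single_frame_stack(self):
        v = VideoStack(np.zeros((8, 8), dtype=np.uint8), frame_rate=30.0)
        assert v.n_frames == 1
        assert v.duration_s == pytest.approx(1 / 30)

    def test_bad_rate_rejected(self):
        with pytest.raises(VideoFormatError):
            VideoStack(np.zeros((2, 8, 8)), frame_rate=0.0)


class TestReadWriteVideo:
    def test_round_trip_with_sidecars(self, tmp_path, rng):
        frames = np.stack([textured_frame(rng) for _ in range(5)])
        white = np.zeros((48, 64, 3), dtype=np.uint8)
        v = VideoStack(frames, frame_rate=15.0, white_light_frame=white)
        path = tmp_path / "vid.tif"
        write_video(v, path)
        back = read_video(path)
        assert np.array_equal(back.frames, frames)
        assert back.frame_rate == 15.0
        assert back.white_light_frame is not None

    def test_default_frame_rate_without_sidecar(self, tmp_path, rng):
        import tifffile

        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.stack([textured_frame(rng) for _ in range(3)]))
        assert read_video(path).frame_rate == 30.0

    def test_missing_file(self, tmp_path):
        with pytest.raises(VideoFormatError):
            read_video(tmp_path / "nope.tif")

    def test_truncated_file(self, tmp_path):
        path = tmp_path / "trunc.tif"
        path.write_bytes(b"II*\x00garbage")
        with pytest.raises(VideoFormatError):
            read_video(path)


class TestStabilize:
    def test_known_shift_recovered(self, rng):
        base = textured_frame(rng)
        frames = [base]
        for k in range(1, 4):
            frames.append(np.roll(base, shift=(k, 0), axis=(0, 1)))
        v = stabilize(VideoStack(np.stack(frames), frame_rate=30.0))
        for k in range(1, 4):
            assert abs(v.offsets[k][0] - (-k)) <= 1
            assert abs(v.offsets[k][1]) <= 1

    def test_identical_frames_zero_offsets(self, rng):
        base = textured_frame(rng)
        v = stabilize(VideoStack(np.stack([base] * 4), frame_rate=30.0))
        assert np.all(v.offsets == 0)

    def test_uniform_frames_unchanged(self):
        frames = np.full((3, 16, 16), 7, dtype=np.uint8)
        v = stabilize(VideoStack(frames, frame_rate=30.0))
        assert np.array_equal(v.frames, frames)
        assert np.all(v.offsets == 0)

    def test_idempotent(self, rng):
        base = textured_frame(rng)
        frames = np.stack([np.roll(base, (k, 2 * k), axis=(0, 1)) for k in range(4)])
        once = stabilize(VideoStack(frames, frame_rate=30.0))
        twice = stabilize(once)
        assert np.all(np.abs(twice.offsets) <= 1)


class TestExtractROICurves:
    def make_line(self):
        return ROILine(vertices=[(24, 4), (24, 60)], spacing_px=10, roi_radius_px=3)

    def test_constant_video_constant_curves(self):
        v = VideoStack(np.full((10, 48, 64), 50, dtype=np.uint8), frame_rate=10.0)
        curves = extract_roi_curves(v, self.make_line())
        assert len(curves) == 6
        for c in curves:
            assert np.allclose(c.intensities, 50.0)

    def test_short_line_single_roi(self):
        v = VideoStack(np.zeros((4, 48, 64), dtype=np.uint8), frame_rate=10.0)
        line = ROILine(vertices=[(24, 10), (24, 14)], spacing_px=100, roi_radius_px=3)
        curves = extract_roi_curves(v, line)
        assert len(curves) == 1
        assert curves[0].meta["centre"] == (24.0, 10.0)

    def test_position_index_increases_along_line(self):
        v = VideoStack(np.zeros((2, 48, 64), dtype=np.uint8), frame_rate=10.0)
        curves = extract_roi_curves(v, self.make_line())
        assert [c.position_index for c in curves] == sorted(
            c.position_index for c in curves
        )

    def test_commutes_with_intensity_scaling(self, rng):
        frames = rng.random((6, 48, 64)) * 100
        v1 = VideoStack(frames, frame_rate=10.0)
        v3 = VideoStack(frames * 3.0, frame_rate=10.0)
        line = self.make_line()
        for a, b in zip(extract_roi_curves(v1, line), extract_roi_curves(v3, line)):
            np.testing.assert_allclose(b.intensities, 3.0 * a.intensities, rtol=1e-12)


class TestExtractPixelCurves:
    def test_block_counting(self):
        v = VideoStack(np.zeros((3, 8, 8), dtype=np.uint8), frame_rate=10.0)
        curves = extract_pixel_curves(v, np.ones((8, 8), dtype=bool), bin=4)
        assert len(curves) == 4
        assert set(curves) == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_empty_mask(self):
        v = VideoStack(np.zeros((3, 8, 8), dtype=np.uint8), frame_rate=10.0)
        assert extract_pixel_curves(v, np.zeros((8, 8), dtype=bool), bin=2) == {}

    def test_mask_excludes_region(self, rng):
        v = VideoStack(rng.random((3, 8, 8)), frame_rate=10.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[:, :4] = True  # right half excluded
        curves = extract_pixel_curves(v, mask, bin=4)
        assert all(bj == 0 for _, bj in curves)

    def test_bin1_returns_pixel_values(self, rng):
        frames = rng.random((5, 4, 4))
        v = VideoStack(frames, frame_rate=10.0)
        curves = extract_pixel_curves(v, np.ones((4, 4), dtype=bool), bin=1)
        np.testing.assert_allclose(curves[(2, 3)].intensities, frames[:, 2, 3])

    def test_weighted_block_means_equal_region_mean(self, rng):
        frames = rng.random((6, 10, 13))
        v = VideoStack(frames, frame_rate=10.0)
        mask = rng.random((10, 13)) > 0.4
        curves = extract_pixel_curves(v, mask, bin=4)
        total = sum(c.intensities * c.meta["n_pixels"] for c in curves.values())
        weight = sum(c.meta["n_pixels"] for c in curves.values())
        region_mean = frames[:, mask].mean(axis=1)
        np.testing.assert_allclose(total / weight, region_mean, atol=1e-6)


class TestCurveCSV:
    def make_curves(self):
        t = np.arange(5) / 10.0
        return [
            PerfusionCurve(t, np.array([0.0, 1.0, 2.5, 2.0, 1.0]), "roi000", 0, "reference"),
            PerfusionCurve(t, np.array([0.1, 0.9, 2.0, 1.5, 0.5]), "roi001", 1, "determinative"),
            PerfusionCurve(t, np.linspace(0, 1, 5), "roi002", 2, "determinative"),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "curves.csv"
        curves = self.make_curves()
        write_curves(curves, path)
        back = read_curves(path)
        assert len(back) == 3
        for a, b in zip(curves, back):
            np.testing.assert_allclose(a.intensities, b.intensities)
            np.testing.assert_allclose(a.times_s, b.times_s)
            assert (a.roi_id, a.position_index, a.source) == (
                b.roi_id, b.position_index, b.source
            )

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_curves([], path)
        text = path.read_text().strip()
        assert text == "time_s,roi_id,position_index,source,intensity"
        assert read_curves(path) == []

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,roi_id,intensity\n0.0,roi000,1.0\n")
        with pytest.raises(CurveFormatError, match="position_index"):
            read_curves(path)

    def test_unsorted_times_resorted(self, tmp_path, caplog):
        path = tmp_path / "unsorted.csv"
        path.write_text(
            "time_s,roi_id,position_index,source,intensity\n"
            "0.2,roi000,0,determinative,3.0\n"
            "0.0,roi000,0,determinative,1.0\n"
            "0.1,roi000,0,determinative,2.0\n"
        )
        import logging

        with caplog.at_level(logging.WARNING):
            curves = read_curves(path)
        np.testing.assert_allclose(curves[0].times_s, [0.0, 0.1, 0.2])
        np.testing.assert_allclose(curves[0].intensities, [1.0, 2.0, 3.0])
        assert any("re-sorting" in r.message for r in caplog.records)
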