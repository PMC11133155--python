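import numpy as np
import pytest

from icgfa import (
    MatchConfig,
    PhantomSpec,
    PreprocessConfig,
    ReferenceProfile,
    gamma_variate,
    make_phantom_video,
)
from icgfa.phantom import KineticParams
from icgfa.pixel_recommender import (
    LABEL_BORDERLINE,
    LABEL_INSUFFICIENT,
    LABEL_OUTSIDE,
    LABEL_SUFFICIENT,
    ScaleFieldMap,
    classify_field,
    fit_all_pixels,
    render_metric_heatmap,
    render_recommendation_overlay,
    save_overlay,
)
from icgfa.curve_match import CurveFitResult


def make_field(briskness_list, frame_shape=(16, 16), bin_size=4, accepted=None):
    accepted = accepted if accepted is not None else [True] * len(briskness_list)
    blocks = {}
    cols = frame_shape[1] // bin_size
    for i, (b, acc) in enumerate(zip(briskness_list, accepted)):
        blocks[(i // cols, i % cols)] = CurveFitResult(
            scale_s=1.0 / b if b > 0 else np.nan,
            shift_tau_s=0.0, agreement=0.9 if acc else 0.3,
            diff_curve_area=0.05, accepted=acc,
        )
    mask = np.ones(frame_shape, dtype=bool)
    return ScaleFieldMap(blocks=blocks, bin_size=bin_size, mask=mask, frame_shape=frame_shape)


class TestClassifyField:
    def test_uniform_briskness_all_sufficient(self):
        cls = classify_field(make_field([1.0] * 16))
        assert np.all(cls.labels == LABEL_SUFFICIENT)
        assert cls.q75_briskness == pytest.approx(1.0)

    def test_all_rejected_all_insufficient(self):
        with pytest.warns(UserWarning, match="no accepted blocks"):
            cls = classify_field(make_field([1.0] * 16, accepted=[False] * 16))
        assert np.all(cls.labels == LABEL_INSUFFICIENT)
        assert cls.q75_briskness is None

    def test_three_group_histogram(self):
        # 40 blocks at 1.0, 40 at 0.5, 20 at 0.1: q75 = 1.0
        brisk = [1.0] * 40 + [0.5] * 40 + [0.1] * 20
        field = make_field(brisk, frame_shape=(40, 40), bin_size=4)
        cls = classify_field(field)
        assert cls.q75_briskness == pytest.approx(1.0)
        labels = cls.labels.ravel()
        assert np.all(labels[:40] == LABEL_SUFFICIENT)
        assert np.all(labels[40:80] == LABEL_BORDERLINE)
        assert np.all(labels[80:] == LABEL_INSUFFICIENT)

    def test_rejected_blocks_not_in_histogram(self):
        brisk = [1.0] * 4 + [100.0] * 4  # huge briskness but rejected
        field = make_field(brisk, frame_shape=(8, 16), bin_size=4,
                           accepted=[True] * 4 + [False] * 4)
        cls = classify_field(field)
        assert cls.q75_briskness == pytest.approx(1.0)
        assert np.all(cls.labels.ravel()[4:] == LABEL_INSUFFICIENT)

    def test_partition_of_masked_area(self):
        rng = np.random.default_rng(0)
        brisk = rng.uniform(0.05, 1.2, 16).tolist()
        cls = classify_field(make_field(brisk))
        inside = cls.labels != LABEL_OUTSIDE
        assert inside.sum() == 16
        assert set(np.unique(cls.labels)) <= {
            LABEL_INSUFFICIENT, LABEL_BORDERLINE, LABEL_SUFFICIENT,
        }

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(1)
        brisk = rng.uniform(0.1, 1.0, 16).tolist()
        f1 = make_field(brisk)
        f2 = make_field(brisk)
        f2.blocks = dict(reversed(list(f2.blocks.items())))
        np.testing.assert_array_equal(
            classify_field(f1).labels, classify_field(f2).labels
        )

    def test_percentile_rank_mode(self):
        brisk = np.linspace(0.1, 1.0, 16).tolist()
        cls = classify_field(make_field(brisk), rule_mode="percentile_rank")
        labels = cls.labels.ravel()
        assert (labels == LABEL_INSUFFICIENT).sum() == 4  # lowest quartile
        assert (labels == LABEL_SUFFICIENT).sum() == 4


class TestFitAllPixels:
    @pytest.fixture()
    def two_zone(self):
        spec = PhantomSpec(
            n_rois=2, ischemia_start_index=1, dilation_gradient=2.0,
            attenuation_gradient=1.0, noise_sigma=0.01,
            duration_s=240.0, rate_hz=5.0, seed=21,
        )
        video, mask, truth = make_phantom_video(spec, width=64, height=32)
        t = np.arange(0, 240, 0.1)
        profile = ReferenceProfile(curve=gamma_variate(spec.baseline, t, source="reference"))
        return spec, video, mask, truth, profile

    def fast_cfgs(self):
        return (
            MatchConfig(s_steps=41, tau_step_s=2.0, tau_min_s=-30, tau_max_s=30),
            PreprocessConfig(resample_hz=2.0, sg_window_s=2.5),
        )

    def test_two_zone_scale_medians(self, two_zone):
        spec, video, mask, truth, profile = two_zone
        match_cfg, pre_cfg = self.fast_cfgs()
        field = fit_all_pixels(profile, video, mask, match_cfg, pre_cfg, bin=8)
        scales = field.scale_grid()
        left = np.nanmedian(scales[:, :4])
        right = np.nanmedian(scales[:, 4:])
        assert left == pytest.approx(1.0, abs=0.15)
        assert right == pytest.approx(2.0, abs=0.3)

    def test_empty_mask_empty_map(self, two_zone):
        _, video, _, _, profile = two_zone
        match_cfg, pre_cfg = self.fast_cfgs()
        field = fit_all_pixels(
            profile, video, np.zeros(video.frame_shape, dtype=bool),
            match_cfg, pre_cfg, bin=8,
        )
        assert field.blocks == {}

    def test_background_blocks_marked_unquantifiable(self, two_zone):
        spec, video, mask, truth, profile = two_zone
        match_cfg, pre_cfg = self.fast_cfgs()
        # mask includes a background row: constant-ish, may be unquantifiable or rejected
        full = np.ones(video.frame_shape, dtype=bool)
        full[mask] = False
        spec2 = PhantomSpec(
            n_rois=2, ischemia_start_index=1, dilation_gradient=2.0,
            attenuation_gradient=1.0, noise_sigma=0.0,
            duration_s=240.0, rate_hz=5.0, seed=21,
        )
        video0, mask0, _ = make_phantom_video(spec2, width=64, height=32)
        bg = np.zeros(video0.frame_shape, dtype=bool)
        bg[0:8, :] = True  # off-band region
        field = fit_all_pixels(profile, video0, bg, match_cfg, pre_cfg, bin=8)
        assert all(not f.accepted for f in field.blocks.values())


class TestRendering:
    def test_constant_grid_single_colour(self):
        frame = np.full((16, 16, 3), 100, dtype=np.uint8)
        grid = np.full((4, 4), 2.0)
        overlay = render_metric_heatmap(grid, frame, bin_size=4)
        assert overlay.image.shape == (16, 16, 3)
        flat = overlay.image.reshape(-1, 3)
        assert np.all(flat == flat[0])

    def test_all_missing_grid_untouched(self):
        frame = np.full((8, 8, 3), 50, dtype=np.uint8)
        overlay = render_metric_heatmap(np.full((2, 2), np.nan), frame, bin_size=4)
        np.testing.assert_array_equal(overlay.image, frame)
        assert overlay.legend == {}

    def test_overlay_dims_match_frame(self):
        frame = np.zeros((33, 47), dtype=np.uint8)  # not divisible by bin
        grid = np.ones((9, 12))
        overlay = render_metric_heatmap(grid, frame, bin_size=4)
        assert overlay.image.shape == (33, 47, 3)

    def test_recommendation_overlay_colours_and_outside(self):
        frame = np.full((16, 16, 3), 10, dtype=np.uint8)
        field = make_field([1.0] * 8 + [0.01] * 4, frame_shape=(16, 16), bin_size=4)
        # leave last row of blocks unclassified (outside)
        cls = classify_field(field)
        overlay = render_recommendation_overlay(cls, frame)
        assert overlay.image.shape == (16, 16, 3)
        top = overlay.image[:8]
        assert top[..., 1].mean() > top[..., 0].mean()  # green dominates sufficient zone
        outside = overlay.image[12:]
        np.testing.assert_array_equal(outside, frame[12:])

    def test_save_overlay_png(self, tmp_path):
        frame = np.zeros((8, 8, 3), dtype=np.uint8)
        overlay = render_metric_heatmap(np.ones((2, 2)), frame, bin_size=4)
        path = tmp_path / "overlay.png"
        save_overlay(overlay, path)
        import imageio.v3 as iio

        back = iio.imread(path)
        assert back.shape == (8, 8, 3)
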