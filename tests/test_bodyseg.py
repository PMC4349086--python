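import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flywalk import bodyseg
from flywalk.bodyseg import (
    SegmentationError,
    binarize_and_close,
    fit_segment_templates,
    moments_align,
    percentile_projection,
    shoulder_width,
    subtract_and_complement,
    watershed_segments,
)
from flywalk.geometry import mass_moments


class TestSubtractComplement:
    def test_frame_equal_to_background_gives_uniform_bright(self):
        bg = np.full((20, 20), 200, np.uint8)
        out = subtract_and_complement(bg.copy(), bg)
        assert (out == 255).all()

    def test_fly_pixels_stay_darker_than_background(self, female_fly):
        seq = female_fly.seq
        out = subtract_and_complement(seq.blue[0], seq.background_blue)
        fg = np.abs(seq.blue[0].astype(int) - seq.background_blue.astype(int)) > 40
        assert out[fg].mean() < out[~fg].mean() - 50

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_and_complement(np.zeros((5, 5)), np.zeros((6, 5)))


class TestMomentsAlign:
    def _blob_frame(self, shift=(0, 0), angle_deg=0.0):
        rr, cc = np.mgrid[0:301, 0:301]
        th = np.radians(angle_deg)
        u = (rr - 150 - shift[0]) * np.cos(th) + (cc - 150 - shift[1]) * np.sin(th)
        v = -(rr - 150 - shift[0]) * np.sin(th) + (cc - 150 - shift[1]) * np.cos(th)
        body = (u / 70) ** 2 + (v / 25) ** 2 <= 1
        img = np.full((301, 301), 255.0)
        img[body] = 60.0
        return img.astype(np.uint8)

    def test_centered_axis_aligned_frame_is_near_identity(self):
        stack = moments_align([self._blob_frame()])
        tf = stack.transforms[0]
        assert abs(tf.centroid[0] - 150) < 1.0 and abs(tf.centroid[1] - 150) < 1.0
        assert abs(np.degrees(tf.angle)) < 0.5

    def test_known_translation_recovered(self):
        stack = moments_align([self._blob_frame(shift=(10, -7))])
        tf = stack.transforms[0]
        assert tf.centroid[0] - 150 == pytest.approx(10, abs=0.5)
        assert tf.centroid[1] - 150 == pytest.approx(-7, abs=0.5)

    def test_known_rotation_recovered(self):
        stack = moments_align([self._blob_frame(angle_deg=20.0)])
        assert np.degrees(stack.transforms[0].angle) == pytest.approx(20.0, abs=0.5)

    def test_aligned_frames_have_vertical_axis(self, female_fly):
        for frame in female_fly.stack.frames:
            mass = 255.0 - frame
            mass[mass < 20] = 0
            _, _, ang = mass_moments(mass)
            assert abs(np.degrees(ang)) < 1.0

    def test_zero_mass_frames_are_skipped(self):
        blank = np.full((50, 50), 255, np.uint8)
        with pytest.raises(SegmentationError):
            moments_align([blank])


class TestPercentileProjection:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), q=st.floats(0, 100))
    def test_matches_per_pixel_sort_oracle(self, seed, q):
        """Projection equals a brute-force per-pixel order statistic."""
        rng = np.random.default_rng(seed)
        stack = rng.integers(0, 256, size=(5, 8, 8)).astype(float)
        got = percentile_projection(stack, q)
        oracle = np.empty((8, 8))
        for r in range(8):
            for c in range(8):
                vals = np.sort(stack[:, r, c])
                pos = q / 100 * (len(vals) - 1)
                lo, hi = int(np.floor(pos)), int(np.ceil(pos))
                oracle[r, c] = vals[lo] + (pos - lo) * (vals[hi] - vals[lo])
        assert np.allclose(got, oracle)

    def test_identical_frames_project_to_themselves(self):
        frame = np.arange(64, dtype=float).reshape(8, 8)
        stack = np.stack([frame] * 4)
        assert np.array_equal(percentile_projection(stack, 95), frame)

    def test_q_zero_is_the_minimum(self):
        rng = np.random.default_rng(1)
        stack = rng.normal(size=(6, 5, 5))
        assert np.allclose(percentile_projection(stack, 0), stack.min(axis=0))

    def test_single_dark_transient_is_removed_at_q95(self):
        stack = np.full((40, 4, 4), 200.0)
        stack[17, 2, 2] = 10.0  # a leg in 1 of 40 frames
        assert percentile_projection(stack, 95)[2, 2] == 200.0

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ValueError):
            percentile_projection(np.zeros((3, 4, 4)), 101)

    def test_moving_legs_leave_no_trace(self, female_fly):
        """Pixels a leg darkens in at most one frame come back bright."""
        frames = female_fly.stack.frames
        proj = percentile_projection(frames, 95)
        mask = binarize_and_close(proj)
        dark_counts = (frames < 100).sum(axis=0)  # leg-level darkness
        transient = (dark_counts == 1) & ~mask
        assert transient.any()  # the legs did move
        assert (proj[transient] >= 100).all()


class TestBinarize:
    def test_one_pixel_bristles_are_removed(self):
        img = np.full((100, 100), 255.0)
        img[30:70, 40:60] = 50.0  # body
        img[50, 60:80] = 50.0  # 1-px bristle
        img[20:30, 50] = 50.0
        mask = binarize_and_close(img, min_area=100)
        assert mask[40:60, 45:55].all()
        assert not mask[50, 70:80].any()
        assert not mask[20:28, 50].any()

    def test_closing_is_idempotent_on_clean_masks(self):
        from skimage import morphology

        img = np.full((80, 80), 255.0)
        img[20:60, 25:55] = 40.0
        once = morphology.closing(img, morphology.disk(2))
        twice = morphology.closing(once, morphology.disk(2))
        assert np.array_equal(once, twice)

    def test_threshold_above_fly_level_is_an_error(self):
        img = np.full((50, 50), 255.0)
        with pytest.raises(SegmentationError, match="no fly"):
            binarize_and_close(img, threshold=10.0)


def _three_lobe_mask(shape=(400, 200)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    c = shape[1] / 2
    head = ((rr - 80) / 28) ** 2 + ((cc - c) / 26) ** 2 <= 1
    thorax = ((rr - 160) / 50) ** 2 + ((cc - c) / 40) ** 2 <= 1
    abd = ((rr - 280) / 80) ** 2 + ((cc - c) / 52) ** 2 <= 1
    return head | thorax | abd


class TestWatershed:
    def test_three_lobes_give_three_ordered_segments(self):
        labels = watershed_segments(_three_lobe_mask())
        assert set(np.unique(labels)) == {0, 1, 2, 3}
        rows = [np.nonzero(labels == k)[0].mean() for k in (1, 2, 3)]
        assert rows[0] < rows[1] < rows[2]
        areas = [(labels == k).sum() for k in (1, 2, 3)]
        assert areas[0] < areas[1] < areas[2]

    def test_head_relabelled_when_mask_is_upside_down(self):
        labels = watershed_segments(_three_lobe_mask()[::-1])
        areas = [(labels == k).sum() for k in (1, 2, 3)]
        assert areas[0] < areas[2]  # label 1 is still the smaller terminal lobe

    def test_single_circle_cannot_be_split(self):
        rr, cc = np.mgrid[0:120, 0:120]
        circle = (rr - 60) ** 2 + (cc - 60) ** 2 <= 40**2
        with pytest.raises(SegmentationError):
            watershed_segments(circle)

    def test_union_of_segments_and_lines_restores_the_mask(self):
        mask = _three_lobe_mask()
        labels = watershed_segments(mask)
        lines = mask & (labels == 0)
        assert ((labels > 0).sum() + lines.sum()) == mask.sum()

    def test_generator_body_recovers_segment_geometry(self, female_fly):
        """Fitted segment centres track the generating ellipse spacing."""
        t = female_fly.truth
        fits = female_fly.model.fits
        got_ht = fits["thorax"].center[0] - fits["head"].center[0]
        got_ta = fits["abdomen"].center[0] - fits["thorax"].center[0]
        assert got_ht == pytest.approx(t.thorax[0] - t.head[0], abs=4.0)
        assert got_ta == pytest.approx(t.abdomen[0] - t.thorax[0], abs=4.0)
        for name, (cu, a, b) in (
            ("head", t.head),
            ("thorax", t.thorax),
            ("abdomen", t.abdomen),
        ):
            assert fits[name].width == pytest.approx(2 * b, rel=0.03)


class TestEllipseFit:
    def test_exact_ellipse_region_recovered(self):
        rr, cc = np.mgrid[0:201, 0:201]
        region = ((rr - 100) / 50) ** 2 + ((cc - 100) / 20) ** 2 <= 1
        labels = np.zeros((201, 201), np.int32)
        labels[region] = 1
        labels[5:12, 5:12] = 2  # dummies so all three segments exist
        labels[5:12, 20:27] = 3
        with pytest.raises(SegmentationError):
            fit_segment_templates(np.where(labels == 1, 1, 0))
        # only the first segment is a real ellipse
        f = fit_segment_templates(labels)["head"]
        assert f.semi_major == pytest.approx(50, abs=1)
        assert f.semi_minor == pytest.approx(20, abs=1)

    def test_circle_has_equal_axes(self):
        rr, cc = np.mgrid[0:101, 0:101]
        labels = np.zeros((101, 101), np.int32)
        labels[(rr - 50) ** 2 + (cc - 50) ** 2 <= 30**2] = 1
        labels[2:9, 2:9] = 2
        labels[2:9, 12:19] = 3
        f = fit_segment_templates(labels)["head"]
        assert f.semi_major == pytest.approx(f.semi_minor, abs=1)


class TestShoulderWidth:
    @pytest.mark.parametrize(
        "width, ref, expected", [(40.0, 40.0, 40.0), (50.0, 40.0, 50.0)]
    )
    def test_template_scale_proportionality(self, width, ref, expected):
        assert shoulder_width(width, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            shoulder_width(40.0, 0.0)

    def test_recovered_sw_tracks_truth(self, female_fly, male_fly):
        for fly in (female_fly, male_fly):
            assert fly.model.sw_px == pytest.approx(fly.truth.sw_true, rel=0.05)
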