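"""Imaging path: homography calibration, landmark projection, polygonal
ROI masks, ROI-mean extraction, and the difference signal."""

import numpy as np
import pytest

from thermoaffect.imaging import (
    CalibrationError,
    LandmarkSet,
    N_LANDMARKS,
    PlanarTransform,
    RecordingMeta,
    ROIMask,
    ThermalFrameStack,
    ThermalTimeSeries,
    build_roi_mask,
    difference_signal,
    extract_roi_series,
    fit_vis_to_ir_transform,
    polygon_mask,
    project_landmarks,
)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def dlt_normal_equations(src, dst):
    """Independent homography oracle: inhomogeneous DLT solved by the
    normal equations instead of lstsq."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    n = len(src)
    a = np.zeros((2 * n, 8))
    b = np.zeros(2 * n)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        a[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        b[2 * i] = u
        a[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i + 1] = v
    h = np.linalg.solve(a.T @ a, a.T @ b)
    return np.append(h, 1.0).reshape(3, 3)


def point_in_polygon_scalar(px, py, poly, eps=1e-9):
    """Scalar even-odd test with boundary-inclusive rule (oracle)."""
    inside = False
    n = len(poly)
    for i in range(n):
        xa, ya = poly[i]
        xb, yb = poly[(i + 1) % n]
        if (ya > py) != (yb > py):
            xin = xa + (py - ya) * (xb - xa) / (yb - ya)
            if px < xin:
                inside = not inside
        seg = max(1.0, float(np.hypot(xb - xa, yb - ya)))
        cross = (xb - xa) * (py - ya) - (yb - ya) * (px - xa)
        if (
            abs(cross) <= eps * seg
            and min(xa, xb) - eps <= px <= max(xa, xb) + eps
            and min(ya, yb) - eps <= py <= max(ya, yb) + eps
        ):
            return True
    return inside


def mask_oracle(poly, shape):
    rows, cols = shape
    out = np.zeros(shape, bool)
    for y in range(rows):
        for x in range(cols):
            out[y, x] = point_in_polygon_scalar(float(x), float(y), poly)
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestFitTransform:
    def test_identity_from_square(self):
        t = fit_vis_to_ir_transform(UNIT_SQUARE, UNIT_SQUARE)
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-9)

    def test_pure_translation_exact(self):
        shifted = UNIT_SQUARE + np.array([5.0, -3.0])
        t = fit_vis_to_ir_transform(UNIT_SQUARE, shifted)
        expected = np.array([[1, 0, 5], [0, 1, -3], [0, 0, 1.0]])
        np.testing.assert_allclose(t.matrix, expected, atol=1e-9)
        reproj = t.apply(UNIT_SQUARE)
        assert np.max(np.abs(reproj - shifted)) < 1e-9

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        true = np.array([[0.9, 0.05, 2.0], [-0.04, 1.1, -1.0], [1e-3, -5e-4, 1.0]])
        src = rng.uniform(0, 10, (8, 2))
        dst = PlanarTransform(true).apply(src) + rng.normal(0, 0.1, (8, 2))
        fitted = fit_vis_to_ir_transform(src, dst).matrix
        oracle = dlt_normal_equations(src, dst)
        assert np.linalg.norm(fitted - oracle) / np.linalg.norm(oracle) < 1e-9
        # and the generator is recovered to noise level: reprojection of a
        # probe grid differs from the true mapping by a few times sigma
        probe = rng.uniform(0, 10, (50, 2))
        err = PlanarTransform(fitted).apply(probe) - PlanarTransform(true).apply(probe)
        assert np.sqrt(np.mean(err**2)) < 3 * 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(CalibrationError):
            fit_vis_to_ir_transform(UNIT_SQUARE[:3], UNIT_SQUARE[:3])

    def test_collinear_pairs_rejected(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(CalibrationError):
            fit_vis_to_ir_transform(src, src * 2.0)

    def test_fit_then_project_roundtrip_noiseless(self):
        rng = np.random.default_rng(3)
        true = np.array([[1.2, 0.1, 4.0], [0.0, 0.8, 7.0], [2e-4, 1e-4, 1.0]])
        src = rng.uniform(0, 10, (4, 2))
        dst = PlanarTransform(true).apply(src)
        t = fit_vis_to_ir_transform(src, dst)
        rms = np.sqrt(np.mean((t.apply(src) - dst) ** 2))
        assert rms <= 1e-6


class TestProjectLandmarks:
    def _landmarks(self, rng):
        return LandmarkSet(rng.uniform(0, 100, (N_LANDMARKS, 2)), "VIS")

    def test_identity_keeps_points_and_retags(self):
        lm = self._landmarks(np.random.default_rng(0))
        out = project_landmarks(lm, PlanarTransform(np.eye(3)))
        assert out.space == "IR"
        np.testing.assert_allclose(out.points, lm.points)

    def test_translation_shifts_every_point(self):
        lm = self._landmarks(np.random.default_rng(1))
        t = PlanarTransform([[1, 0, 4.5], [0, 1, -2.0], [0, 0, 1]])
        out = project_landmarks(lm, t)
        np.testing.assert_allclose(out.points, lm.points + [4.5, -2.0])

    def test_projective_matches_per_point_multiply(self):
        rng = np.random.default_rng(2)
        lm = self._landmarks(rng)
        m = np.array([[1.1, 0.2, 3.0], [-0.1, 0.9, 5.0], [1e-3, 2e-3, 1.0]])
        out = project_landmarks(lm, PlanarTransform(m))
        for p_in, p_out in zip(lm.points, out.points):
            h = m @ np.append(p_in, 1.0)
            np.testing.assert_allclose(p_out, h[:2] / h[2], rtol=1e-12)

    def test_out_of_frame_points_flagged_not_dropped(self):
        pts = np.full((N_LANDMARKS, 2), 10.0)
        pts[0] = (500.0, 10.0)  # beyond 320 cols
        lm = LandmarkSet(pts, "VIS")
        out = project_landmarks(lm, PlanarTransform(np.eye(3)), RecordingMeta())
        assert out.out_of_frame[0] and not out.out_of_frame[1:].any()
        assert len(out.points) == N_LANDMARKS

    def test_ir_input_is_a_usage_error(self):
        lm = LandmarkSet(np.zeros((N_LANDMARKS, 2)), "IR")
        with pytest.raises(ValueError, match="VIS"):
            project_landmarks(lm, PlanarTransform(np.eye(3)))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

class TestMasks:
    def _landmarks_with(self, vertices, indices):
        pts = np.full((N_LANDMARKS, 2), 5.0)
        for i, v in zip(indices, vertices):
            pts[i] = v
        return LandmarkSet(pts, "IR")

    def test_axis_aligned_square_has_nine_pixels(self):
        poly = [(0.0, 0.0), (2.0, 0.0), (2.0, 2.0), (0.0, 2.0)]
        mask = polygon_mask(np.array(poly), (10, 10))
        assert mask.sum() == 9
        assert mask[:3, :3].all()

    def test_triangle_matches_even_odd_oracle(self):
        poly = np.array([(0.0, 0.0), (4.0, 0.0), (0.0, 4.0)])
        mask = polygon_mask(poly, (8, 8))
        np.testing.assert_array_equal(mask, mask_oracle(poly, (8, 8)))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_polygons_match_oracle_small_frames(self, seed):
        rng = np.random.default_rng(seed)
        n_vert = rng.integers(3, 8)
        poly = rng.uniform(-5, 68, (n_vert, 2))
        shape = (64, 64)
        mask = polygon_mask(poly, shape)
        np.testing.assert_array_equal(mask, mask_oracle(poly, shape))

    def test_rasterization_is_idempotent(self):
        rng = np.random.default_rng(9)
        poly = rng.uniform(0, 30, (5, 2))
        m1 = polygon_mask(poly, (32, 32))
        m2 = polygon_mask(poly, (32, 32))
        np.testing.assert_array_equal(m1, m2)

    def test_polygon_outside_frame_empty_and_degraded(self):
        meta = RecordingMeta(ir_shape=(32, 32))
        lm = self._landmarks_with(
            [(-50.0, -50.0), (-40.0, -50.0), (-45.0, -40.0)], (21, 22, 27)
        )
        roi = build_roi_mask(lm, "glabella", meta)
        assert roi.empty and roi.degraded and not roi.usable

    def test_default_roi_polygons_use_configured_landmarks(self):
        meta = RecordingMeta(ir_shape=(64, 64))
        lm = self._landmarks_with(
            [(10.0, 10.0), (20.0, 10.0), (15.0, 20.0)], (21, 22, 27)
        )
        roi = build_roi_mask(lm, "glabella", meta)
        np.testing.assert_allclose(roi.polygon, [[10, 10], [20, 10], [15, 20]])
        assert not roi.degraded and roi.mask.sum() > 0

    def test_custom_indices_and_minimum_vertices(self):
        meta = RecordingMeta(ir_shape=(32, 32))
        lm = self._landmarks_with([(1.0, 1.0), (9.0, 1.0), (5.0, 9.0)], (0, 1, 2))
        roi = build_roi_mask(lm, "nose_tip", meta, indices=(0, 1, 2))
        assert roi.mask.sum() > 0
        with pytest.raises(ValueError):
            build_roi_mask(lm, "nose_tip", meta, indices=(0, 1))


# ---------------------------------------------------------------------------
# series extraction
# ---------------------------------------------------------------------------

def _stack(frames, fs=10.0):
    frames = np.asarray(frames, float)
    meta = RecordingMeta(sampling_rate=fs, ir_shape=frames.shape[1:])
    return ThermalFrameStack(frames, np.arange(len(frames)) / fs, meta)


def _full_mask(shape, name="nose_tip"):
    return ROIMask(name, np.array([(0, 0), (shape[1], 0), (0, shape[0])]),
                   np.ones(shape, bool))


class TestExtraction:
    def test_uniform_frame_gives_its_value(self):
        stack = _stack(np.full((3, 4, 4), 1000.0))
        masks = [_full_mask((4, 4)) for _ in range(3)]
        series = extract_roi_series(stack, masks)
        np.testing.assert_allclose(series.values, 1000.0)
        assert not series.missing.any()

    def test_checkerboard_mean_equals_pixel_loop(self):
        frame = np.arange(16.0).reshape(4, 4) * 7.0 % 13.0
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        roi = ROIMask("nose_tip", np.array([(1, 1), (2, 1), (2, 2), (1, 2)]), mask)
        series = extract_roi_series(_stack(frame[None]), [roi])
        total, count = 0.0, 0
        for y in range(4):
            for x in range(4):
                if mask[y, x]:
                    total += frame[y, x]
                    count += 1
        assert series.values[0] == pytest.approx(total / count, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_frames_match_pixel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frames = rng.uniform(5000, 9000, (4, 16, 16))
        masks = []
        for i in range(4):
            m = rng.random((16, 16)) < 0.4
            m[0, 0] = True  # never empty
            masks.append(ROIMask("glabella", np.array([(0, 0), (1, 0), (0, 1)]), m))
        series = extract_roi_series(_stack(frames), masks)
        for i in range(4):
            vals = [
                frames[i, y, x]
                for y in range(16)
                for x in range(16)
                if masks[i].mask[y, x]
            ]
            assert series.values[i] == pytest.approx(
                sum(vals) / len(vals), rel=1e-9
            )

    def test_empty_mask_yields_missing_sample_same_length(self):
        frames = np.full((3, 4, 4), 500.0)
        masks = [_full_mask((4, 4)) for _ in range(3)]
        masks[1] = ROIMask(
            "nose_tip", np.array([(0, 0), (1, 0), (0, 1)]), np.zeros((4, 4), bool)
        )
        series = extract_roi_series(_stack(frames), masks)
        assert series.n == 3
        assert series.missing[1] and not series.missing[0]
        assert np.isnan(series.values[1])

    def test_shape_mismatch_rejected(self):
        stack = _stack(np.zeros((1, 4, 4)))
        with pytest.raises(ValueError, match="shape"):
            extract_roi_series(stack, [_full_mask((5, 5))])


class TestDifferenceSignal:
    def _series(self, values, missing=None):
        n = len(values)
        return ThermalTimeSeries(
            np.arange(n) / 10.0, values,
            np.zeros(n, bool) if missing is None else missing,
        )

    def test_identical_series_give_zero(self):
        s = self._series(np.full(50, 7000.0))
        np.testing.assert_allclose(difference_signal(s, s).values, 0.0)

    def test_constant_offset_preserved(self):
        g = self._series(np.linspace(7000, 7010, 50))
        nose = self._series(g.values + 5.0)
        np.testing.assert_allclose(difference_signal(nose, g).values, 5.0)

    def test_elementwise_subtraction_and_missing_propagation(self):
        rng = np.random.default_rng(12)
        a_vals, b_vals = rng.normal(7000, 3, 40), rng.normal(7000, 3, 40)
        a_miss = rng.random(40) < 0.1
        b_miss = rng.random(40) < 0.1
        a = self._series(np.where(a_miss, np.nan, a_vals), a_miss)
        b = self._series(np.where(b_miss, np.nan, b_vals), b_miss)
        d = difference_signal(a, b)
        for i in range(40):
            if a_miss[i] or b_miss[i]:
                assert d.missing[i]
            else:
                assert d.values[i] == pytest.approx(a_vals[i] - b_vals[i], rel=1e-12)

    def test_timestamp_mismatch_rejected(self):
        a = self._series(np.zeros(10))
        b = ThermalTimeSeries(np.arange(10) / 5.0, np.zeros(10))
        with pytest.raises(ValueError):
            difference_signal(a, b)
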