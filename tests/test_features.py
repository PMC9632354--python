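import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drowse.errors import DegenerateGeometryError
from drowse.features import (
    FEATURE_ORDER,
    EyeCalibration,
    FeatureFrame,
    WindowStats,
    blink_frequency,
    calibrate_eye,
    eav,
    eoa,
    extract_features,
    is_eye_closed,
    lid_distance,
    mav,
    moa,
    s_ar,
    s_mp,
    scalarize,
    yawn_frequency,
)

# canonical open eye: corners at (0,0) and (4,0), lid pairs one unit apart
EYE = np.array([[0, 0], [1, 1], [1, -1], [3, 1], [3, -1], [4, 0]], dtype=float)
# mouth: corners (0,0),(4,0); vertical gaps 2, 3, 2 at quarter points
MOUTH = np.array(
    [[0, 0], [1, 1], [2, 1.5], [3, 1], [4, 0], [3, -1], [2, -1.5], [1, -1]],
    dtype=float,
)


def transform(pts, angle=0.0, scale=1.0, shift=(0.0, 0.0)):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return scale * pts @ R.T + np.asarray(shift)


class TestEyeFeatures:
    def test_eav_hand_example(self):
        # |p5-p4| = |p2-p3| = 2, |p6-p1| = 4
        assert eav(EYE) == pytest.approx([0.5, 0.5])

    def test_eav_closed_eye_is_zero(self):
        closed = EYE.copy()
        closed[[2, 4], 1] = closed[[1, 3], 1]  # p3=p2, p5=p4 heights
        closed[[1, 3], 1] = closed[[2, 4], 1]
        closed[:, 1] = 0.0
        assert eav(closed) == pytest.approx([0.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(-np.pi, np.pi),
        st.floats(0.1, 10.0),
        st.floats(-100, 100),
        st.floats(-100, 100),
    )
    def test_ratio_features_rigid_and_scale_invariant(self, angle, scale, dx, dy):
        eye2 = transform(EYE, angle, scale, (dx, dy))
        mouth2 = transform(MOUTH, angle, scale, (dx, dy))
        assert eav(eye2) == pytest.approx(eav(EYE), abs=1e-9)
        assert eoa(eye2) == pytest.approx(eoa(EYE), abs=1e-9)
        assert mav(mouth2) == pytest.approx(mav(MOUTH), abs=1e-9)
        assert moa(mouth2) == pytest.approx(moa(MOUTH), abs=1e-9)

    def test_eoa_hand_example(self):
        # p2=(1,1) above the corner line through (0,0)-(4,0): arcsin(1/sqrt(2))
        assert eoa(EYE) == pytest.approx(np.pi / 4)

    def test_eoa_zero_on_corner_line(self):
        flat = EYE.copy()
        flat[1] = [1.0, 0.0]
        assert eoa(flat) == 0.0

    def test_eoa_bounded(self, rng):
        for _ in range(100):
            pts = EYE + rng.normal(0, 0.3, EYE.shape)
            assert 0.0 <= eoa(pts) <= np.pi / 2

    def test_eoa_degenerate_apex(self):
        bad = EYE.copy()
        bad[1] = bad[0]
        with pytest.raises(DegenerateGeometryError):
            eoa(bad)

    def test_coincident_corners_rejected(self):
        bad = EYE.copy()
        bad[5] = bad[0]
        with pytest.raises(DegenerateGeometryError):
            eav(bad)

    def test_s_ar_hand_example(self):
        calib = EyeCalibration(a_max=4.0, b_max=2.0)
        # current canthus distance 2, lid distance 1 -> (2*1)/(4*2)
        half = transform(EYE, scale=0.5)
        assert s_ar(half, calib) == pytest.approx(0.25)

    def test_s_ar_fully_open_is_one(self):
        calib = EyeCalibration(a_max=4.0, b_max=2.0)
        assert s_ar(EYE, calib) == pytest.approx(1.0)

    def test_s_ar_closed_is_zero(self):
        calib = EyeCalibration(a_max=4.0, b_max=2.0)
        flat = EYE.copy()
        flat[:, 1] = 0.0
        assert s_ar(flat, calib) == 0.0

    def test_bad_calibration_rejected(self):
        with pytest.raises(ValueError):
            EyeCalibration(a_max=0.0, b_max=1.0)


class TestMouthFeatures:
    def test_mav_hand_example(self):
        # verticals (|M4-M6|, |M3-M7|, |M2-M8|) = (2, 3, 2) over width 4
        assert mav(MOUTH) == pytest.approx([0.5, 0.75, 0.5])

    def test_mav_closed_mouth(self):
        flat = MOUTH.copy()
        flat[:, 1] = 0.0
        assert mav(flat) == pytest.approx([0.0, 0.0, 0.0])

    def test_moa_hand_example(self):
        pts = MOUTH.copy()
        pts[2] = [2.0, 2.0]  # M3 at (2,2): arcsin(2/sqrt(8))
        assert moa(pts) == pytest.approx(np.pi / 4)

    def test_moa_zero_on_corner_line(self):
        pts = MOUTH.copy()
        pts[2] = [2.0, 0.0]
        assert moa(pts) == 0.0

    def test_s_mp_hand_example(self):
        pts = MOUTH.copy()
        pts[7, 0], pts[0, 0] = 3.0, 1.0  # |x_M8 - x_M1| = 2
        pts[6, 1], pts[2, 1] = -2.0, 2.0  # |y_M7 - y_M3| = 4
        assert s_mp(pts) == pytest.approx(8.0)

    def test_s_mp_zero_when_x_aligned(self):
        pts = MOUTH.copy()
        pts[7, 0] = pts[0, 0]
        assert s_mp(pts) == 0.0

    def test_s_mp_translation_invariant(self, rng):
        shift = rng.uniform(-50, 50, 2)
        assert s_mp(MOUTH + shift) == pytest.approx(s_mp(MOUTH))


class TestClosureAndFrequencies:
    CALIB = EyeCalibration(a_max=4.0, b_max=2.0)

    def scaled_lid(self, factor):
        pts = EYE.copy()
        pts[[1, 3], 1] = factor
        pts[[2, 4], 1] = -factor
        return pts

    def test_fully_closed_detected(self):
        assert is_eye_closed(self.scaled_lid(0.0), self.CALIB)

    def test_fully_open_not_closed(self):
        assert not is_eye_closed(EYE, self.CALIB)

    def test_threshold_rule(self):
        # lid distance 19% of baseline -> closed; 21% -> open
        assert is_eye_closed(self.scaled_lid(0.19), self.CALIB)
        assert not is_eye_closed(self.scaled_lid(0.21), self.CALIB)

    def test_blink_frequency_counts_closed_frames(self, rng):
        flags = np.array([1, 0, 0, 1, 1, 0, 0, 0, 0, 0], bool)
        assert blink_frequency(flags) == pytest.approx(0.3)
        random_flags = rng.random(500) < 0.37
        assert blink_frequency(random_flags) == pytest.approx(
            sum(bool(f) for f in random_flags) / 500
        )

    def test_blink_frequency_extremes_and_empty(self):
        assert blink_frequency(np.zeros(10, bool)) == 0.0
        assert blink_frequency(np.ones(10, bool)) == 1.0
        with pytest.raises(ValueError):
            blink_frequency(np.array([], bool))

    def test_yawn_frequency_counts_long_runs(self):
        mid = np.zeros(900)
        mid[100:160] = 0.9  # 4 s at 15 fps
        assert yawn_frequency(mid, fps=15.0) == pytest.approx(60 / 900)

    def test_yawn_frequency_never_opened(self):
        assert yawn_frequency(np.zeros(900), fps=15.0) == 0.0

    def test_speech_burst_excluded_by_duration_gate(self):
        mid = np.zeros(900)
        mid[100:115] = 0.9  # 1 s burst above threshold
        assert yawn_frequency(mid, fps=15.0) == 0.0


class TestScalarize:
    FRAME = FeatureFrame(
        eav=(0.4, 0.6),
        eoa=0.7,
        s_ar=0.8,
        mav=(0.1, 0.2, 0.3),
        moa=0.35,
        s_mp=12.0,
        pitch=5.0,
        yaw=-2.0,
        roll=1.0,
    )
    WINDOW = WindowStats(f_blink=0.25, f_yawn=0.05, n_frames=900)

    def test_component_means_and_order(self):
        vec = scalarize(self.FRAME, self.WINDOW)
        assert len(vec) == 11
        expected = dict(
            eav=0.5, mav=0.2, s_ar=0.8, s_mp=12.0, pitch=5.0, yaw=-2.0,
            roll=1.0, eoa=0.7, moa=0.35, f_blink=0.25, f_yawn=0.05,
        )
        for name, value in expected.items():
            assert vec[FEATURE_ORDER.index(name)] == pytest.approx(value)

    def test_non_finite_rejected(self):
        bad = FeatureFrame(
            eav=(np.nan, 0.6), eoa=0.7, s_ar=0.8, mav=(0.1, 0.2, 0.3),
            moa=0.35, s_mp=12.0, pitch=5.0, yaw=-2.0, roll=1.0,
        )
        with pytest.raises(ValueError):
            scalarize(bad, self.WINDOW)

    def test_window_stats_validated(self):
        with pytest.raises(ValueError):
            WindowStats(f_blink=1.5, f_yawn=0.0, n_frames=10)
        with pytest.raises(ValueError):
            WindowStats(f_blink=0.5, f_yawn=0.0, n_frames=0)


class TestExtractFeatures:
    def test_blink_frequency_separates_states(self, awake_session, fatigued_session):
        dfa = extract_features(awake_session, estimate_pose=False)
        dff = extract_features(fatigued_session, estimate_pose=False)
        assert dff["f_blink"].iloc[-1] > dfa["f_blink"].iloc[-1]

    def test_columns_and_labels(self, fatigued_session):
        df = extract_features(fatigued_session, estimate_pose=False)
        assert list(df.columns) == ["t", *FEATURE_ORDER, "label"]
        assert set(df["label"]) == {1}

    def test_calibration_from_stream(self, awake_session):
        calib = calibrate_eye(awake_session.eye_pts)
        assert calib.a_max > 0 and calib.b_max > 0
        # the open-eye lid gap should be near the calibrated maximum
        open_lid = np.median(lid_distance(awake_session.eye_pts))
        assert open_lid > 0.5 * calib.baseline_open
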