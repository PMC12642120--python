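"""Frame-level visual feature definitions: EAR/blinks, gaze, affect, head."""

import numpy as np
import pytest

from povmark.visual import (
    BlinkEvent,
    affect_durations,
    classify_gaze_frame,
    compute_ear,
    detect_blinks,
    ear_series,
    gaze_class_codes,
    gaze_durations,
    head_metrics,
    ocular_metrics,
    social_smiling_duration,
)

from conftest import make_stream
from oracles import brute_force_blinks


HAND_POINTS = np.array([(0, 0), (1, 1), (3, 1), (4, 0), (3, -1), (1, -1)], float)


class TestComputeEar:
    def test_hand_worked_example(self):
        # vertical distances 2 and 2, horizontal 4 -> (2+2)/(2*4) = 0.5
        assert compute_ear(HAND_POINTS) == pytest.approx(0.5)

    def test_closed_eye_limit_is_zero(self):
        pts = HAND_POINTS.copy()
        pts[1] = pts[5]  # p2 = p6
        pts[2] = pts[4]  # p3 = p5
        assert compute_ear(pts) == 0.0

    @pytest.mark.parametrize("scale", [7.0, 0.01, 1234.5])
    def test_scale_invariance(self, scale):
        assert compute_ear(HAND_POINTS * scale) == pytest.approx(0.5)

    def test_similarity_transform_invariance(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(6, 2)) * 10
            pts[3] = pts[0] + rng.normal(size=2) * 5 + np.array([1.0, 0.0])
            base = compute_ear(pts)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = rng.uniform(0.1, 10)
            shift = rng.normal(size=2) * 100
            moved = pts @ rot.T * scale + shift
            assert compute_ear(moved) == pytest.approx(base, abs=1e-9)

    def test_coincident_corners_raise(self):
        pts = HAND_POINTS.copy()
        pts[3] = pts[0]
        with pytest.raises(ValueError, match="degenerate"):
            compute_ear(pts)


class TestEarSeries:
    def test_mean_of_two_eyes(self):
        stream = make_stream(ear=[0.3, 0.3])
        stream.eye_right *= 2.0  # still EAR-identical (scale-invariant)
        # plant different EARs: left 0.30, right 0.20
        from povmark.synth import landmarks_from_ear

        stream.eye_left = landmarks_from_ear(np.array([0.30, 0.30]))
        stream.eye_right = landmarks_from_ear(np.array([0.20, 0.20]))
        np.testing.assert_allclose(ear_series(stream), [0.25, 0.25], atol=1e-12)

    def test_missing_frame_propagates(self):
        missing = {"eye": np.array([False, True, False])}
        stream = make_stream(ear=[0.3, 0.3, 0.3], missing=missing)
        out = ear_series(stream)
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2]]).any()

    def test_single_eye_fallback(self):
        stream = make_stream(ear=[0.3])
        stream.eye_right[:] = stream.eye_right[0, 0]  # degenerate right eye
        assert ear_series(stream)[0] == pytest.approx(0.3)

    def test_planted_trace_recovered(self, rng):
        from povmark.synth import landmarks_from_ear

        trace = rng.uniform(0.05, 0.45, size=200)
        stream = make_stream(ear=trace)
        stream.eye_left = landmarks_from_ear(trace, rng)
        stream.eye_right = landmarks_from_ear(trace, rng)
        np.testing.assert_allclose(ear_series(stream), trace, atol=1e-9)


class TestDetectBlinks:
    def test_two_complete_events(self):
        events = detect_blinks([0.3, 0.3, 0.1, 0.1, 0.3, 0.15, 0.3])
        assert events == [BlinkEvent(2, 3, True), BlinkEvent(5, 5, True)]

    def test_constant_open_series_empty(self):
        assert detect_blinks([0.3] * 20) == []

    def test_boundary_run_incomplete(self):
        events = detect_blinks([0.1, 0.1, 0.3])
        assert events == [BlinkEvent(0, 1, False)]

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            detect_blinks([np.nan, np.nan])

    def test_missing_frame_splits_run(self):
        events = detect_blinks([0.3, 0.1, np.nan, 0.1, 0.3])
        assert [(e.start_frame, e.end_frame, e.complete) for e in events] == [
            (1, 1, False),
            (3, 3, False),
        ]

    def test_matches_brute_force_oracle_on_random_series(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 60))
            ear = rng.uniform(0.05, 0.4, size=n)
            ear[rng.random(n) < 0.1] = np.nan
            if np.isnan(ear).all():
                continue
            got = [(e.start_frame, e.end_frame, e.complete) for e in detect_blinks(ear)]
            assert got == brute_force_blinks(ear)


class TestOcularMetrics:
    def test_hand_worked_example(self):
        # closed frames {2,3} and {5}; both runs complete at 30 fps
        ear = np.array([0.3, 0.3, 0.1, 0.1, 0.3, 0.15, 0.3])
        count, dur, _ = ocular_metrics(ear, fps=30.0)
        assert count == 2
        assert dur == pytest.approx((3 / 2) / 30.0)

    def test_no_blinks_convention(self):
        ear = np.full(10, 0.31)
        count, dur, openness = ocular_metrics(ear, fps=30.0)
        assert (count, dur) == (0, 0.0)
        assert openness == pytest.approx(0.31)

    def test_threshold_frames_in_neither_set(self):
        # EAR exactly 0.20 is neither open (>0.2) nor closed (<0.2)
        ear = np.array([0.3, 0.2, 0.1, 0.2, 0.3])
        count, dur, openness = ocular_metrics(ear, fps=1.0)
        assert count == 0  # run bounded by 0.2-frames, not open frames
        assert openness == pytest.approx(0.3)

    def test_incomplete_runs_count_in_duration_numerator(self):
        # boundary run (2 frames) + complete run (1 frame): numerator 3, count 1
        ear = np.array([0.1, 0.1, 0.3, 0.15, 0.3])
        count, dur, _ = ocular_metrics(ear, fps=30.0)
        assert count == 1
        assert dur == pytest.approx(3 / 1 / 30.0)

    def test_no_open_frames_gives_missing_openness(self):
        _, _, openness = ocular_metrics(np.array([0.1, 0.15]), fps=30.0)
        assert np.isnan(openness)


class TestGaze:
    @pytest.mark.parametrize(
        "pitch, yaw, expected",
        [
            (0.17, 0.0, "right"),  # boundary inclusive
            (-0.17, 0.0, "left"),
            (0.0, 0.0, "center"),
            (0.169, 0.0, "center"),
            (0.10, 0.36, "invalid"),  # |yaw| beyond validity bound
            (0.10, 0.35, "center"),  # |yaw| exactly at the bound is valid
            (np.nan, 0.0, "invalid"),
        ],
    )
    def test_frame_classification(self, pitch, yaw, expected):
        assert classify_gaze_frame(pitch, yaw) == expected

    def test_hand_worked_durations(self):
        pitch = np.concatenate(
            [np.zeros(450), np.full(300, 0.3), np.full(100, -0.3), np.zeros(50)]
        )
        yaw = np.zeros(900)
        yaw[850:] = 0.4  # 50 invalid frames
        stream = make_stream(ear=np.full(900, 0.3), gaze_pitch=pitch, gaze_yaw=yaw)
        d = gaze_durations(stream, fps=30.0)
        assert d.center_s == pytest.approx(15.0)
        assert d.right_s == pytest.approx(10.0)
        assert d.left_s == pytest.approx(100 / 30)
        assert d.invalid_s == pytest.approx(50 / 30)

    def test_all_center(self):
        stream = make_stream(ear=np.full(900, 0.3))
        d = gaze_durations(stream, fps=30.0)
        assert d == (0.0, 30.0, 0.0, 0.0)

    def test_duration_conservation_on_random_streams(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 400))
            stream = make_stream(
                ear=np.full(n, 0.3),
                gaze_pitch=rng.uniform(-1, 1, n),
                gaze_yaw=rng.uniform(-1, 1, n),
                missing={"gaze": rng.random(n) < 0.2},
            )
            d = gaze_durations(stream, fps=30.0)
            assert sum(d) == pytest.approx(n / 30.0, abs=1e-9)


class TestAffect:
    def test_hand_worked_example(self):
        n = 900
        au12 = np.zeros(n)
        au12[:300] = 0.9
        au06 = np.zeros(n)
        au06[:120] = 0.8
        au_other = np.zeros(n)
        au_other[300:400] = 0.7  # 100 frames non-neutral via other AUs
        stream = make_stream(ear=np.full(n, 0.3), au12=au12, au06=au06, au_other=au_other)
        d = affect_durations(stream, fps=30.0)
        assert d.smiling_s == pytest.approx(10.0)
        assert d.happy_s == pytest.approx(4.0)
        assert d.neutral_s == pytest.approx(500 / 30)

    def test_all_zero_aus_fully_neutral(self):
        stream = make_stream(ear=np.full(900, 0.3))
        d = affect_durations(stream, fps=30.0)
        assert d == (0.0, 0.0, 30.0)

    def test_happy_requires_coactivation(self):
        n = 100
        stream = make_stream(ear=np.full(n, 0.3), au06=np.full(n, 0.9))
        d = affect_durations(stream, fps=30.0)
        assert d.happy_s == 0.0 and d.smiling_s == 0.0
        assert d.neutral_s == 0.0  # au06 active -> not neutral either

    def test_set_algebra_on_random_streams(self, rng):
        from povmark.visual import _affect_masks, GAZE_CENTER

        for _ in range(50):
            n = int(rng.integers(10, 300))
            stream = make_stream(
                ear=np.full(n, 0.3),
                au12=rng.random(n),
                au06=rng.random(n),
                au_other=rng.random(n),
                gaze_pitch=rng.uniform(-0.5, 0.5, n),
                gaze_yaw=rng.uniform(-0.5, 0.5, n),
                missing={"au": rng.random(n) < 0.1},
            )
            smiling, happy, neutral, _ = _affect_masks(stream, 0.5)
            center = gaze_class_codes(stream) == GAZE_CENTER
            social = smiling & center
            assert not np.any(happy & ~smiling)  # happy subset of smiling
            assert not np.any(social & ~(smiling & center))
            assert not np.any(neutral & (smiling | happy))

    def test_social_smiling_hand_example(self):
        n = 900
        au12 = np.zeros(n)
        au12[:300] = 0.9
        pitch = np.zeros(n)
        pitch[:100] = 0.3  # first 100 smiling frames look right, not center
        stream = make_stream(ear=np.full(n, 0.3), au12=au12, gaze_pitch=pitch)
        assert social_smiling_duration(stream, fps=30.0) == pytest.approx(200 / 30)

    def test_social_zero_when_smiling_only_lateral(self):
        n = 100
        au12 = np.zeros(n)
        au12[:50] = 0.9
        pitch = np.zeros(n)
        pitch[:50] = -0.4
        stream = make_stream(ear=np.full(n, 0.3), au12=au12, gaze_pitch=pitch)
        assert social_smiling_duration(stream, fps=30.0) == 0.0

    def test_social_equals_smiling_when_subset_of_center(self):
        n = 100
        au12 = np.zeros(n)
        au12[10:40] = 0.9
        stream = make_stream(ear=np.full(n, 0.3), au12=au12)
        assert social_smiling_duration(stream, fps=30.0) == pytest.approx(
            affect_durations(stream, fps=30.0).smiling_s
        )


class TestHeadMetrics:
    def test_hand_worked_example(self):
        head = np.array([[0, 0, 0], [2, 0, 0], [2, 6, 0]], float)
        stream = make_stream(ear=np.full(3, 0.3), head=head)
        total, rapid = head_metrics(stream, fps=30.0)
        assert total == pytest.approx(8.0)
        assert rapid == 1

    def test_constant_pose(self):
        stream = make_stream(ear=np.full(10, 0.3), head=np.ones((10, 3)))
        assert head_metrics(stream) == (0.0, 0.0)

    def test_exact_five_degrees_not_rapid(self):
        head = np.array([[0, 0, 0], [0, 5.0, 0]], float)
        stream = make_stream(ear=np.full(2, 0.3), head=head)
        total, rapid = head_metrics(stream)
        assert total == pytest.approx(5.0)
        assert rapid == 0

    def test_pairs_straddling_missing_skipped(self):
        head = np.array([[0, 0, 0], [50, 0, 0], [52, 0, 0]], float)
        stream = make_stream(
            ear=np.full(3, 0.3), head=head, missing={"head": np.array([False, True, False])}
        )
        total, rapid = head_metrics(stream)
        assert np.isnan(total) and np.isnan(rapid)

    def test_fewer_than_two_valid_frames_missing(self):
        stream = make_stream(
            ear=np.full(2, 0.3), missing={"head": np.array([True, False])}
        )
        total, rapid = head_metrics(stream)
        assert np.isnan(total) and np.isnan(rapid)
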