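import numpy as np
import pytest

from povmark.datamodel import SegmentStream
from povmark.synth import CohortConfig, generate_cohort, noiseless_config


def make_stream(
    n=90,
    fps=30.0,
    ear=None,
    gaze_pitch=None,
    gaze_yaw=None,
    au12=None,
    au06=None,
    au_other=None,
    head=None,
    missing=None,
    participant_id="t",
    segment_index=1,
):
    """Hand-buildable SegmentStream for unit tests (landmarks encode the EAR)."""
    from povmark.synth import landmarks_from_ear

    ear = np.full(n, 0.3) if ear is None else np.asarray(ear, float)
    n = len(ear)
    pts = landmarks_from_ear(ear)
    gaze = np.column_stack(
        [
            np.zeros(n) if gaze_pitch is None else np.asarray(gaze_pitch, float),
            np.zeros(n) if gaze_yaw is None else np.asarray(gaze_yaw, float),
        ]
    )
    au = {
        "au12": np.zeros(n) if au12 is None else np.asarray(au12, float),
        "au06": np.zeros(n) if au06 is None else np.asarray(au06, float),
        "au_other_max": np.zeros(n) if au_other is None else np.asarray(au_other, float),
    }
    head_pose = np.zeros((n, 3)) if head is None else np.asarray(head, float)
    return SegmentStream(
        participant_id=participant_id,
        segment_index=segment_index,
        fps=fps,
        eye_left=pts.copy(),
        eye_right=pts.copy(),
        head_pose=head_pose,
        gaze=gaze,
        au=au,
        missing=missing or {},
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small default-parameter cohort (6 vs 6, 2 segments) for pipeline tests."""
    cfg = CohortConfig(n_mdd=6, n_hc=6, segments=2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free cohort whose pipeline output must match planted truth."""
    cfg = noiseless_config(n_mdd=3, n_hc=3, segments=2, seed=5)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
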