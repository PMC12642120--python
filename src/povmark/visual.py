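"""Visual behavioral features from per-frame streams.

Implements the frame-level definitions used throughout the pipeline:

* eye-aspect-ratio (EAR) blink detection — EAR = (d(p2,p6) + d(p3,p5)) /
  (2 d(p1,p4)); a blink is a maximal run of frames with EAR < 0.2 that is
  preceded and followed by open (EAR > 0.2) frames;
* angular gaze classification — the horizontal gaze component (the gaze
  network's "pitch" under the egocentric camera convention) is thresholded at
  +/-0.17 rad into left/center/right, with frames at |vertical| > 0.35 rad
  marked invalid and excluded from aggregation;
* AU-based affect durations — smiling = AU12 active, happy (Duchenne) =
  AU6 and AU12 co-active, neutral = no major expressive AU active, social
  smiling = smiling during center gaze;
* head-movement metrics — total absolute frame-to-frame angular change summed
  over pitch/yaw/roll, and a count of rapid movements (any-axis change > 5
  degrees between consecutive frames).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .datamodel import SegmentStream

EAR_THRESHOLD = 0.20
GAZE_PITCH_THRESHOLD_RAD = 0.17
GAZE_YAW_VALID_RAD = 0.35
RAPID_HEAD_THRESHOLD_DEG = 5.0
AU_ACTIVE_THRESHOLD = 0.5

#: Major expressive AUs whose absence defines a neutral frame. On disk their
#: joint activation is compressed to the single channel ``au_other_max``
#: (maximum over the set excluding AU6/AU12).
MAJOR_EXPRESSIVE_AUS = (1, 2, 4, 5, 6, 9, 12, 15, 17, 20, 25, 26)

GAZE_LEFT, GAZE_CENTER, GAZE_RIGHT, GAZE_INVALID = 0, 1, 2, 3
_GAZE_NAMES = {GAZE_LEFT: "left", GAZE_CENTER: "center", GAZE_RIGHT: "right",
               GAZE_INVALID: "invalid"}


@dataclass(frozen=True)
class BlinkEvent:
    """One maximal sub-threshold EAR run (inclusive frame bounds)."""

    start_frame: int
    end_frame: int
    complete: bool

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


class GazeDurations(NamedTuple):
    left_s: float
    center_s: float
    right_s: float
    invalid_s: float


class AffectDurations(NamedTuple):
    smiling_s: float
    happy_s: float
    neutral_s: float


def compute_ear(points: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Eye aspect ratio of six eye landmarks p1..p6.

    Points are ordered outer corner (p1), upper lid (p2, p3), inner corner
    (p4), lower lid (p5, p6); EAR = (d(p2,p6) + d(p3,p5)) / (2 d(p1,p4)).
    Invariant under rigid rotation, translation and uniform scaling.
    """
    p = np.asarray(points, dtype=float)
    if p.shape != (6, 2):
        raise ValueError(f"expected 6 planar points, got shape {p.shape}")
    horiz = np.linalg.norm(p[0] - p[3])
    if horiz <= 0:
        raise ValueError("degenerate eye geometry: corners p1 and p4 coincide")
    v1 = np.linalg.norm(p[1] - p[5])
    v2 = np.linalg.norm(p[2] - p[4])
    return float((v1 + v2) / (2.0 * horiz))


def _ear_batch(points: np.ndarray) -> np.ndarray:
    """Vectorized EAR over a (n, 6, 2) landmark array (NaN where degenerate)."""
    horiz = np.linalg.norm(points[:, 0] - points[:, 3], axis=1)
    v1 = np.linalg.norm(points[:, 1] - points[:, 5], axis=1)
    v2 = np.linalg.norm(points[:, 2] - points[:, 4], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (v1 + v2) / (2.0 * horiz)
    out[horiz <= 0] = np.nan
    return out


def ear_series(stream: SegmentStream) -> np.ndarray:
    """Per-frame EAR: mean of the two per-eye ratios, NaN where missing.

    When one eye's landmarks are unusable in a frame the other eye's EAR is
    used alone; frames with the eye channel masked (or both eyes degenerate)
    are NaN.
    """
    left = _ear_batch(stream.eye_left)
    right = _ear_batch(stream.eye_right)
    both = np.stack([left, right])
    ok = ~np.isnan(both)
    count = ok.sum(axis=0)
    total = np.where(ok, both, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ear = np.where(count > 0, total / count, np.nan)
    ear[stream.missing["eye"]] = np.nan
    return ear


def detect_blinks(
    ear: np.ndarray | Sequence[float], threshold: float = EAR_THRESHOLD
) -> list[BlinkEvent]:
    """Maximal runs of frames with EAR < threshold, ordered, non-overlapping.

    A run is ``complete`` (a full blink cycle) only when the immediately
    adjacent frames on both sides exist within the segment, are observed, and
    are open (EAR > threshold); runs touching the segment boundary or a
    missing frame are reported with ``complete=False``. Missing (NaN) frames
    split runs — short dropouts are expected to have been interpolated
    upstream.
    """
    ear = np.asarray(ear, dtype=float)
    if ear.size == 0:
        raise ValueError("empty EAR series")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    valid = ~np.isnan(ear)
    if not valid.any():
        raise ValueError("all-missing EAR series")
    closed = valid & (ear < threshold)
    events: list[BlinkEvent] = []
    n = len(ear)
    i = 0
    while i < n:
        if not closed[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and closed[j + 1]:
            j += 1
        open_before = i > 0 and valid[i - 1] and ear[i - 1] > threshold
        open_after = j < n - 1 and valid[j + 1] and ear[j + 1] > threshold
        events.append(BlinkEvent(i, j, open_before and open_after))
        i = j + 1
    return events


def ocular_metrics(
    ear: np.ndarray | Sequence[float],
    events: list[BlinkEvent] | None = None,
    fps: float = 30.0,
    threshold: float = EAR_THRESHOLD,
) -> tuple[int, float, float]:
    """(blink_count, blink_duration_s, eye_openness) from an EAR series.

    blink_count counts complete blink cycles; blink_duration_s divides the
    total number of closed (EAR < threshold) frames — including incomplete
    boundary runs — by the blink count and the frame rate, and is 0 when no
    complete blink occurred; eye_openness is the mean EAR over open
    (EAR > threshold) frames, NaN when no frame is open. Frames at exactly
    the threshold are neither open nor closed and enter neither numerator.
    """
    ear = np.asarray(ear, dtype=float)
    if events is None:
        events = detect_blinks(ear, threshold)
    valid = ~np.isnan(ear)
    blink_count = sum(e.complete for e in events)
    closed_frames = int(np.sum(valid & (ear < threshold)))
    blink_duration_s = (
        closed_frames / blink_count / fps if blink_count > 0 else 0.0
    )
    open_vals = ear[valid & (ear > threshold)]
    eye_openness = float(open_vals.mean()) if open_vals.size else float("nan")
    return blink_count, blink_duration_s, eye_openness


def classify_gaze_frame(
    gaze_pitch: float,
    gaze_yaw: float,
    pitch_thr: float = GAZE_PITCH_THRESHOLD_RAD,
    yaw_valid: float = GAZE_YAW_VALID_RAD,
) -> str:
    """Classify one gaze frame into left/center/right/invalid.

    Right if pitch >= +pitch_thr, left if pitch <= -pitch_thr, center if
    |pitch| < pitch_thr; invalid when |yaw| exceeds the validity bound or the
    angles are not finite (boundaries inclusive exactly as stated: |yaw| equal
    to the bound is still valid, pitch equal to the threshold is lateral).
    """
    if not (np.isfinite(gaze_pitch) and np.isfinite(gaze_yaw)):
        return "invalid"
    if abs(gaze_yaw) > yaw_valid:
        return "invalid"
    if gaze_pitch >= pitch_thr:
        return "right"
    if gaze_pitch <= -pitch_thr:
        return "left"
    return "center"


def gaze_class_codes(
    stream: SegmentStream,
    pitch_thr: float = GAZE_PITCH_THRESHOLD_RAD,
    yaw_valid: float = GAZE_YAW_VALID_RAD,
) -> np.ndarray:
    """Vectorized per-frame gaze class codes (0=left 1=center 2=right 3=invalid)."""
    pitch = stream.gaze[:, 0]
    yaw = stream.gaze[:, 1]
    invalid = (
        stream.missing["gaze"]
        | ~np.isfinite(pitch)
        | ~np.isfinite(yaw)
        | (np.abs(yaw) > yaw_valid)
    )
    codes = np.full(stream.n_frames, GAZE_CENTER, dtype=np.int8)
    codes[pitch >= pitch_thr] = GAZE_RIGHT
    codes[pitch <= -pitch_thr] = GAZE_LEFT
    codes[invalid] = GAZE_INVALID
    return codes


def gaze_durations(
    stream: SegmentStream,
    fps: float | None = None,
    pitch_thr: float = GAZE_PITCH_THRESHOLD_RAD,
    yaw_valid: float = GAZE_YAW_VALID_RAD,
) -> GazeDurations:
    """Per-class gaze durations in seconds; the four durations sum to the span."""
    fps = fps or stream.fps
    codes = gaze_class_codes(stream, pitch_thr, yaw_valid)
    counts = np.bincount(codes, minlength=4)
    return GazeDurations(
        left_s=counts[GAZE_LEFT] / fps,
        center_s=counts[GAZE_CENTER] / fps,
        right_s=counts[GAZE_RIGHT] / fps,
        invalid_s=counts[GAZE_INVALID] / fps,
    )


def _affect_masks(
    stream: SegmentStream, thr: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(smiling, happy, neutral, observed) frame masks."""
    observed = ~stream.missing["au"]
    au12 = np.nan_to_num(stream.au["au12"], nan=-1.0)
    au06 = np.nan_to_num(stream.au["au06"], nan=-1.0)
    other = np.nan_to_num(stream.au["au_other_max"], nan=2.0)
    smiling = observed & (au12 >= thr)
    happy = smiling & (au06 >= thr)
    neutral = observed & (au12 < thr) & (au06 < thr) & (other < thr)
    return smiling, happy, neutral, observed


def affect_durations(
    stream: SegmentStream,
    fps: float | None = None,
    au_active_thr: float = AU_ACTIVE_THRESHOLD,
) -> AffectDurations:
    """Smiling / happy (Duchenne) / neutral durations in seconds.

    Smiling frames have AU12 active (>= threshold); happy frames additionally
    have AU6 active; neutral frames have no major expressive AU active.
    Frames with the AU channel missing enter none of the three numerators.
    """
    fps = fps or stream.fps
    smiling, happy, neutral, _ = _affect_masks(stream, au_active_thr)
    return AffectDurations(
        smiling_s=int(smiling.sum()) / fps,
        happy_s=int(happy.sum()) / fps,
        neutral_s=int(neutral.sum()) / fps,
    )


def social_smiling_duration(
    stream: SegmentStream,
    fps: float | None = None,
    au_active_thr: float = AU_ACTIVE_THRESHOLD,
    pitch_thr: float = GAZE_PITCH_THRESHOLD_RAD,
    yaw_valid: float = GAZE_YAW_VALID_RAD,
) -> float:
    """Seconds of simultaneous smiling (AU12 active) and center gaze."""
    fps = fps or stream.fps
    smiling, _, _, _ = _affect_masks(stream, au_active_thr)
    center = gaze_class_codes(stream, pitch_thr, yaw_valid) == GAZE_CENTER
    return int((smiling & center).sum()) / fps


def head_metrics(
    stream: SegmentStream,
    fps: float | None = None,
    rapid_thr_deg: float = RAPID_HEAD_THRESHOLD_DEG,
) -> tuple[float, float]:
    """(total_head_movement_deg, rapid_head_movement_count).

    Total movement is the cumulative sum of absolute frame-to-frame angular
    changes over all three axes; a rapid movement is a consecutive frame pair
    whose largest single-axis change strictly exceeds ``rapid_thr_deg``.
    Pairs straddling a missing frame are skipped; with fewer than two
    contiguous valid frames both metrics are NaN.
    """
    valid = ~stream.missing["head"]
    pose = stream.head_pose
    pair_ok = valid[:-1] & valid[1:]
    if not pair_ok.any():
        return float("nan"), float("nan")
    deltas = np.abs(np.diff(pose, axis=0))[pair_ok]
    total = float(deltas.sum())
    rapid = int((deltas.max(axis=1) > rapid_thr_deg).sum())
    return total, float(rapid)


def extract_visual_features(
    stream: SegmentStream,
    ear_threshold: float = EAR_THRESHOLD,
    au_active_thr: float = AU_ACTIVE_THRESHOLD,
    pitch_thr: float = GAZE_PITCH_THRESHOLD_RAD,
    yaw_valid: float = GAZE_YAW_VALID_RAD,
    rapid_thr_deg: float = RAPID_HEAD_THRESHOLD_DEG,
) -> dict[str, float]:
    """All 12 visual features of one segment as a name->value record (NaN = missing)."""
    fps = stream.fps
    gaze = gaze_durations(stream, fps, pitch_thr, yaw_valid)
    affect = affect_durations(stream, fps, au_active_thr)
    social = social_smiling_duration(stream, fps, au_active_thr, pitch_thr, yaw_valid)
    total_head, rapid = head_metrics(stream, fps, rapid_thr_deg)
    try:
        ear = ear_series(stream)
        events = detect_blinks(ear, ear_threshold)
        blink_count, blink_dur, openness = ocular_metrics(ear, events, fps, ear_threshold)
    except ValueError:  # all frames missing in the eye channel
        blink_count, blink_dur, openness = float("nan"), float("nan"), float("nan")
    return {
        "center_gaze_s": gaze.center_s,
        "right_gaze_s": gaze.right_s,
        "left_gaze_s": gaze.left_s,
        "smiling_s": affect.smiling_s,
        "happy_s": affect.happy_s,
        "neutral_s": affect.neutral_s,
        "social_smiling_s": social,
        "blink_count": float(blink_count),
        "blink_duration_s": blink_dur,
        "eye_openness": openness,
        "total_head_movement_deg": total_head,
        "rapid_head_movements": rapid,
    }
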