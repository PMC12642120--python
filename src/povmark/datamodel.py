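"""Core data structures for the behavioral-marker pipeline.

The pipeline consumes intermediate per-frame streams that upstream video/audio
extractors would emit (eye landmarks, head-pose angles, gaze angles, facial
action-unit activations, voice-activity labels, word timestamps) and produces
15 named behavioral features per participant, organized a priori into five
domains (gaze, facial affect, ocular physiology, head movement, speech).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

#: The 15 behavioral features, in canonical column order.
FEATURES: tuple[str, ...] = (
    "center_gaze_s",
    "right_gaze_s",
    "left_gaze_s",
    "smiling_s",
    "happy_s",
    "neutral_s",
    "social_smiling_s",
    "blink_count",
    "blink_duration_s",
    "eye_openness",
    "total_head_movement_deg",
    "rapid_head_movements",
    "response_latency_ms",
    "silence_ratio",
    "word_count",
)

#: A-priori five-domain partition of the 15 features (3+4+3+2+3).
DOMAINS: dict[str, tuple[str, ...]] = {
    "gaze": ("center_gaze_s", "right_gaze_s", "left_gaze_s"),
    "affect": ("smiling_s", "happy_s", "neutral_s", "social_smiling_s"),
    "ocular": ("blink_count", "blink_duration_s", "eye_openness"),
    "head": ("total_head_movement_deg", "rapid_head_movements"),
    "speech": ("response_latency_ms", "silence_ratio", "word_count"),
}

#: Inverse map feature -> domain.
FEATURE_DOMAIN: dict[str, str] = {f: d for d, fs in DOMAINS.items() for f in fs}

LABELS: tuple[str, str] = ("MDD", "HC")

#: Per-frame channel groups carried by a SegmentStream (each with its own
#: missingness mask).
CHANNEL_GROUPS: tuple[str, ...] = ("eye", "head", "gaze", "au")

#: Which channel group informs each feature domain for participant-level QC.
#: (Speech availability is tracked separately, per speech segment.)
DOMAIN_CHANNEL: dict[str, str] = {
    "gaze": "gaze",
    "affect": "au",
    "ocular": "eye",
    "head": "head",
}


@dataclass(frozen=True)
class DomainSpec:
    """One feature domain with its Bonferroni-adjusted significance level."""

    name: str
    members: tuple[str, ...]
    family_alpha: float = 0.05

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def alpha(self) -> float:
        """Domain-wise Bonferroni threshold alpha_domain = family_alpha / m."""
        return self.family_alpha / self.m


def domain_specs(family_alpha: float = 0.05) -> dict[str, DomainSpec]:
    return {
        name: DomainSpec(name, members, family_alpha)
        for name, members in DOMAINS.items()
    }


class Word(NamedTuple):
    """One word-level transcript token with speaker attribution."""

    token: str
    onset_s: float
    offset_s: float
    speaker: str  # "participant" | "interviewer"


@dataclass
class SegmentStream:
    """Per-frame visual channels for one participant-segment.

    Frame index is 0-based; the time of frame k is k / fps (half-open
    frame-time convention). Landmark coordinates are image pixels (x right,
    y down); the eye-aspect ratio is scale-invariant so the unit is
    immaterial. Gaze angles follow the egocentric-camera convention in which
    the *pitch* component carries horizontal gaze (positive = participant
    looking to their right of the interviewer) and *yaw* the vertical one.

    Missing data is carried as one boolean mask per channel group
    (``eye``, ``head``, ``gaze``, ``au``); masked frames hold NaN values.
    """

    participant_id: str
    segment_index: int
    fps: float
    eye_left: np.ndarray  # (n, 6, 2) landmark points p1..p6
    eye_right: np.ndarray  # (n, 6, 2)
    head_pose: np.ndarray  # (n, 3) pitch/yaw/roll, degrees
    gaze: np.ndarray  # (n, 2) pitch/yaw, radians
    au: dict[str, np.ndarray] = field(default_factory=dict)  # au06/au12/au_other_max
    missing: dict[str, np.ndarray] = field(default_factory=dict)

    AU_KEYS = ("au06", "au12", "au_other_max")

    @property
    def n_frames(self) -> int:
        return int(self.eye_left.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def __post_init__(self) -> None:
        for key in self.AU_KEYS:
            self.au.setdefault(key, np.zeros(self.n_frames))
        for group in CHANNEL_GROUPS:
            self.missing.setdefault(group, np.zeros(self.n_frames, dtype=bool))
        self.validate()

    def validate(self) -> None:
        n = self.n_frames
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not 1 <= int(self.segment_index):
            raise ValueError(f"segment_index must be >= 1, got {self.segment_index}")
        shapes = {
            "eye_left": (self.eye_left, (n, 6, 2)),
            "eye_right": (self.eye_right, (n, 6, 2)),
            "head_pose": (self.head_pose, (n, 3)),
            "gaze": (self.gaze, (n, 2)),
        }
        for name, (arr, shape) in shapes.items():
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
        for key in self.AU_KEYS:
            arr = self.au[key]
            if arr.shape != (n,):
                raise ValueError(f"au[{key}]: expected shape ({n},), got {arr.shape}")
            observed = arr[~self.missing["au"]]
            observed = observed[~np.isnan(observed)]
            if observed.size and (observed.min() < 0 or observed.max() > 1):
                raise ValueError(f"au[{key}]: activations must lie in [0, 1]")
        for group in CHANNEL_GROUPS:
            mask = self.missing[group]
            if mask.shape != (n,) or mask.dtype != bool:
                raise ValueError(f"missing[{group}]: expected boolean shape ({n},)")


@dataclass
class SpeechSegment:
    """Voice-activity labels and word timestamps for one answer segment.

    VAD labels live on a uniform hop grid (nominally 30 ms analysis windows
    with a 10 ms hop; one boolean label per hop). ``question_end_s`` anchors
    the response-latency measurement; ``answer_window`` bounds the silence
    ratio and word count.
    """

    participant_id: str
    segment_index: int
    vad: np.ndarray  # (n_hops,) bool speech labels
    hop_s: float
    question_end_s: float
    answer_start_s: float
    answer_end_s: float
    words: list[Word] = field(default_factory=list)
    t0_s: float = 0.0  # time of the first hop frame
    window_s: float = 0.03

    def __post_init__(self) -> None:
        self.vad = np.asarray(self.vad, dtype=bool)
        if self.hop_s <= 0:
            raise ValueError("hop_s must be positive")
        if self.answer_start_s > self.answer_end_s:
            raise ValueError("answer window start must not exceed its end")
        for w in self.words:
            if w.onset_s > w.offset_s:
                raise ValueError(f"word {w.token!r}: onset after offset")

    @property
    def answer_window(self) -> tuple[float, float]:
        return (self.answer_start_s, self.answer_end_s)


@dataclass
class FeatureMatrix:
    """Participants x 15 features, with labels and missingness.

    ``data`` is indexed by participant id with exactly the :data:`FEATURES`
    columns (float; NaN encodes missing). ``labels`` is an aligned Series of
    "MDD"/"HC". The feature->domain mapping is the module-level constant
    :data:`DOMAINS`.
    """

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.data = self.data.reindex(columns=list(FEATURES)).astype(float)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate participant ids: {dupes}")
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"missing label for participants: {missing}")
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask, True where a feature is absent."""
        return self.data.isna()

    def group(self, label: str) -> pd.DataFrame:
        return self.data.loc[self.labels == label]

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in LABELS}
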