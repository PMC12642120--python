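"""Missing-data handling, exclusion rules, and participant-level aggregation.

Three nested quality gates mirror the recording-quality workflow:

1. frame level — dropouts of at most 2 consecutive frames (at 30 FPS) are
   repaired by linear interpolation when valid neighbors exist on both sides;
2. segment level — a segment whose worst channel group still has >= 10%
   missing frames is excluded outright;
3. participant level — a participant with >= 20% missing data in a feature
   domain is excluded from that domain's group (inferential) analyses; the
   classification path instead retains the participant and imputes inside
   each training fold.

Feature values from the retained segments are averaged into one vector per
participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    CHANNEL_GROUPS,
    DOMAIN_CHANNEL,
    FEATURES,
    FeatureMatrix,
    SegmentStream,
)

INTERP_MAX_GAP_FRAMES = 2
SEGMENT_EXCLUDE_AT = 0.10
PARTICIPANT_EXCLUDE_AT = 0.20


def interpolate_dropouts(
    values: np.ndarray,
    missing: np.ndarray,
    max_gap_frames: int = INTERP_MAX_GAP_FRAMES,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fill short missing runs by linear interpolation.

    Runs of at most ``max_gap_frames`` missing frames with observed neighbors
    on both sides are filled component-wise; longer runs and runs touching the
    series edge stay missing. Observed frames are never altered. Returns
    (filled values, updated mask, number of filled frames).
    """
    values = np.asarray(values, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    out = values.copy()
    mask = missing.copy()
    n = len(mask)
    filled = 0
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        run_len = j - i + 1
        if i > 0 and j < n - 1 and run_len <= max_gap_frames:
            left, right = out[i - 1], out[j + 1]
            for k in range(1, run_len + 1):
                out[i - 1 + k] = left + (right - left) * (k / (run_len + 1))
            mask[i : j + 1] = False
            filled += run_len
        i = j + 1
    return out, mask, filled


def interpolate_stream(
    stream: SegmentStream, max_gap_frames: int = INTERP_MAX_GAP_FRAMES
) -> tuple[SegmentStream, dict[str, int]]:
    """Apply dropout interpolation to every channel group of a stream."""
    filled_counts: dict[str, int] = {}
    eye = np.concatenate(
        [stream.eye_left.reshape(-1, 12), stream.eye_right.reshape(-1, 12)], axis=1
    )
    eye, eye_mask, filled_counts["eye"] = interpolate_dropouts(
        eye, stream.missing["eye"], max_gap_frames
    )
    head, head_mask, filled_counts["head"] = interpolate_dropouts(
        stream.head_pose, stream.missing["head"], max_gap_frames
    )
    gaze, gaze_mask, filled_counts["gaze"] = interpolate_dropouts(
        stream.gaze, stream.missing["gaze"], max_gap_frames
    )
    au_stack = np.column_stack([stream.au[k] for k in SegmentStream.AU_KEYS])
    au_stack, au_mask, filled_counts["au"] = interpolate_dropouts(
        au_stack, stream.missing["au"], max_gap_frames
    )
    n = stream.n_frames
    out = SegmentStream(
        participant_id=stream.participant_id,
        segment_index=stream.segment_index,
        fps=stream.fps,
        eye_left=eye[:, :12].reshape(n, 6, 2),
        eye_right=eye[:, 12:].reshape(n, 6, 2),
        head_pose=head,
        gaze=gaze,
        au={k: np.clip(au_stack[:, i], 0.0, 1.0)
            for i, k in enumerate(SegmentStream.AU_KEYS)},
        missing={"eye": eye_mask, "head": head_mask, "gaze": gaze_mask, "au": au_mask},
    )
    return out, filled_counts


def segment_qc(
    stream: SegmentStream, exclude_at: float = SEGMENT_EXCLUDE_AT
) -> tuple[bool, str, dict[str, float]]:
    """Keep/exclude decision for one (already interpolated) segment.

    The worst channel group decides: the segment is excluded iff the maximum
    per-group missing fraction reaches ``exclude_at`` (inclusive ">=").
    Returns (excluded, reason, per-group missing fractions).
    """
    fractions = {g: float(stream.missing[g].mean()) for g in CHANNEL_GROUPS}
    worst_group = max(fractions, key=fractions.get)
    worst = fractions[worst_group]
    if worst >= exclude_at:
        reason = f"missing fraction {worst:.3f} in channel group '{worst_group}'"
        return True, reason, fractions
    return False, "", fractions


def participant_domain_qc(
    domain_missing: dict[str, float], exclude_at: float = PARTICIPANT_EXCLUDE_AT
) -> dict[str, bool]:
    """Per-domain inclusion flags from per-domain missing fractions.

    A domain is excluded (flag False) for the participant iff its missing
    fraction reaches ``exclude_at`` (inclusive ">="). Group statistics use
    complete cases per domain; the ML path ignores these flags and imputes.
    """
    return {d: frac < exclude_at for d, frac in domain_missing.items()}


def aggregate_participant(records: list[dict[str, float]]) -> dict[str, float]:
    """Average per-segment feature records into one participant vector.

    Each feature is the arithmetic mean over the segments where it is
    observed; a feature missing in every retained segment stays NaN. With no
    retained segments the vector is all-missing.
    """
    out: dict[str, float] = {}
    keys: list[str] = []
    for rec in records:
        for k in rec:
            if k not in keys:
                keys.append(k)
    for k in keys:
        vals = [rec[k] for rec in records if k in rec and np.isfinite(rec[k])]
        out[k] = float(np.mean(vals)) if vals else float("nan")
    return out


def assemble_matrix(
    vectors: dict[str, dict[str, float]], labels: dict[str, str]
) -> FeatureMatrix:
    """Stack participant feature vectors into a FeatureMatrix."""
    ids = list(vectors)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    data = pd.DataFrame.from_dict(vectors, orient="index")
    lab = pd.Series({pid: labels[pid] for pid in ids})
    return FeatureMatrix(data=data, labels=lab)


@dataclass
class QCReport:
    """Per-segment and per-participant quality-control outcomes."""

    segments: dict[str, dict] = field(default_factory=dict)  # "pid/seg" -> record
    participants: dict[str, dict] = field(default_factory=dict)

    def domain_included(self, pid: str, domain: str) -> bool:
        rec = self.participants.get(pid)
        if rec is None:
            return True
        return bool(rec["domain_included"].get(domain, True))

    def included_ids(self, domain: str) -> list[str]:
        return [p for p in self.participants if self.domain_included(p, domain)]

    def to_dict(self) -> dict:
        return {"segments": self.segments, "participants": self.participants}


def qc_participant(
    streams: list[SegmentStream],
    speech_present: list[bool],
    visual_records: list[dict[str, float]],
    speech_records: list[dict[str, float]],
    segment_exclude_at: float = SEGMENT_EXCLUDE_AT,
    participant_exclude_at: float = PARTICIPANT_EXCLUDE_AT,
    manual_exclude: list[bool] | None = None,
) -> tuple[dict[str, float], dict]:
    """Run the segment and participant gates for one participant.

    ``streams`` must already be interpolated and aligned with the per-segment
    ``visual_records``/``speech_records``. Returns the aggregated feature
    vector and a QC record (segment decisions, per-domain missing fractions
    and inclusion flags). Speech availability is binary per segment (the
    upstream audio either produced a usable VAD/transcript or did not).
    """
    manual_exclude = manual_exclude or [False] * len(streams)
    seg_records = []
    kept_visual: list[dict[str, float]] = []
    kept_fracs: list[dict[str, float]] = []
    for stream, vis, manual in zip(streams, visual_records, manual_exclude):
        excluded, reason, fractions = segment_qc(stream, segment_exclude_at)
        if manual and not excluded:
            excluded, reason = True, "manual exclusion (severe artifact)"
        seg_records.append(
            {
                "segment_index": stream.segment_index,
                "excluded": excluded,
                "reason": reason,
                "missing_fractions": fractions,
            }
        )
        if not excluded:
            kept_visual.append(vis)
            kept_fracs.append(fractions)

    kept_speech = [rec for rec, ok in zip(speech_records, speech_present) if ok]
    n_segments = len(streams)
    domain_missing: dict[str, float] = {}
    for domain, group in DOMAIN_CHANNEL.items():
        if kept_fracs:
            # residual missingness in retained segments plus wholly lost segments
            per_seg = [f[group] for f in kept_fracs]
            lost = n_segments - len(kept_fracs)
            domain_missing[domain] = float(
                (np.sum(per_seg) + lost) / n_segments
            )
        else:
            domain_missing[domain] = 1.0
    domain_missing["speech"] = float(
        1.0 - (len(kept_speech) / n_segments if n_segments else 0.0)
    )
    included = participant_domain_qc(domain_missing, participant_exclude_at)

    vector = aggregate_participant(kept_visual + kept_speech)
    for feat in FEATURES:
        vector.setdefault(feat, float("nan"))
    record = {
        "segments": seg_records,
        "n_segments_kept": len(kept_visual),
        "domain_missing": domain_missing,
        "domain_included": included,
    }
    return vector, record
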