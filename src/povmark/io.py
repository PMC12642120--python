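"""Readers and writers for the on-disk interchange formats.

All formats are plain UTF-8 CSV/JSON with "." decimals and an empty cell for
missing, chosen for unambiguous cross-language interchange:

* segment CSV — one row per frame: ``frame``, 24 eye-landmark coordinates
  (``eyeL_p1x`` .. ``eyeR_p6y``), ``head_pitch_deg``/``head_yaw_deg``/
  ``head_roll_deg``, ``gaze_pitch_rad``/``gaze_yaw_rad``, ``au06``/``au12``/
  ``au_other_max``. A channel group is missing at a frame iff any of its
  cells is empty there.
* speech CSV — a stacked two-section table with a ``record`` discriminator:
  ``vad`` rows carry (``t_start_s``, ``is_speech``), ``word`` rows carry
  (``token``, ``onset_s``, ``offset_s``, ``speaker``).
* cohort manifest JSON — participants with label/age/sex and per-segment file
  references plus the question-end anchor and answer window.
* feature matrix CSV — wide, one row per participant: id, label, 15 features.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    FEATURES,
    LABELS,
    FeatureMatrix,
    SegmentStream,
    SpeechSegment,
    Word,
)


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


_EYE_COLS = [
    f"eye{side}_p{i}{ax}" for side in ("L", "R") for i in range(1, 7) for ax in ("x", "y")
]
_HEAD_COLS = ["head_pitch_deg", "head_yaw_deg", "head_roll_deg"]
_GAZE_COLS = ["gaze_pitch_rad", "gaze_yaw_rad"]
_AU_COLS = ["au06", "au12", "au_other_max"]
SEGMENT_COLUMNS = ["frame"] + _EYE_COLS + _HEAD_COLS + _GAZE_COLS + _AU_COLS

_GROUP_COLS = {
    "eye": _EYE_COLS,
    "head": _HEAD_COLS,
    "gaze": _GAZE_COLS,
    "au": _AU_COLS,
}


def write_segment_stream(stream: SegmentStream, path: str | Path) -> None:
    n = stream.n_frames
    df = pd.DataFrame(index=range(n))
    df["frame"] = np.arange(n)
    eye = np.concatenate(
        [stream.eye_left.reshape(n, 12), stream.eye_right.reshape(n, 12)], axis=1
    )
    df[_EYE_COLS] = eye
    df[_HEAD_COLS] = stream.head_pose
    df[_GAZE_COLS] = stream.gaze
    for key in _AU_COLS:
        df[key] = stream.au[key]
    # Masked frames are emitted as empty cells for the whole channel group.
    for group, cols in _GROUP_COLS.items():
        mask = stream.missing[group]
        if mask.any():
            df.loc[mask, cols] = np.nan
    df.to_csv(path, index=False, float_format="%.12g")


def read_segment_stream(
    path: str | Path,
    participant_id: str = "",
    segment_index: int = 1,
    fps: float = 30.0,
) -> SegmentStream:
    """Read a per-frame segment CSV.

    Unparseable or absent cells become missing-mask entries, never fabricated
    values. Raises :class:`FormatError` for a malformed header, a non-uniform
    frame index, or non-positive fps.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed beyond repair
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing_cols = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    if fps <= 0:
        raise FormatError(f"{path}: fps must be positive, got {fps}")
    n = len(df)
    if n == 0:
        raise FormatError(f"{path}: empty frame table")
    frames = pd.to_numeric(df["frame"], errors="coerce").to_numpy()
    if np.isnan(frames).any() or not np.array_equal(frames, np.arange(n)):
        raise FormatError(f"{path}: column 'frame' must be the uniform index 0..{n - 1}")

    num = df[SEGMENT_COLUMNS[1:]].apply(pd.to_numeric, errors="coerce")
    missing = {
        group: num[cols].isna().any(axis=1).to_numpy()
        for group, cols in _GROUP_COLS.items()
    }
    # NaN out whole groups at masked frames so partial garbage cannot leak in.
    for group, cols in _GROUP_COLS.items():
        num.loc[missing[group], cols] = np.nan

    stream = SegmentStream(
        participant_id=participant_id or path.stem,
        segment_index=segment_index,
        fps=fps,
        eye_left=num[_EYE_COLS[:12]].to_numpy().reshape(n, 6, 2),
        eye_right=num[_EYE_COLS[12:]].to_numpy().reshape(n, 6, 2),
        head_pose=num[_HEAD_COLS].to_numpy(),
        gaze=num[_GAZE_COLS].to_numpy(),
        au={k: num[k].to_numpy() for k in _AU_COLS},
        missing=missing,
    )
    return stream


def write_speech_segment(seg: SpeechSegment, path: str | Path) -> None:
    n = len(seg.vad)
    vad = pd.DataFrame(
        {
            "record": "vad",
            "t_start_s": seg.t0_s + np.arange(n) * seg.hop_s,
            "is_speech": seg.vad.astype(int),
            "token": "",
            "onset_s": np.nan,
            "offset_s": np.nan,
            "speaker": "",
        }
    )
    words = pd.DataFrame(
        {
            "record": "word",
            "t_start_s": np.nan,
            "is_speech": np.nan,
            "token": [w.token for w in seg.words],
            "onset_s": [w.onset_s for w in seg.words],
            "offset_s": [w.offset_s for w in seg.words],
            "speaker": [w.speaker for w in seg.words],
        }
    )
    pd.concat([vad, words], ignore_index=True).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_speech_segment(
    path: str | Path,
    participant_id: str = "",
    segment_index: int = 1,
    question_end_s: float = 0.0,
    answer_start_s: float = 0.0,
    answer_end_s: float = np.inf,
) -> SpeechSegment:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in ("record", "t_start_s", "is_speech", "token", "onset_s", "offset_s", "speaker"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    vad_rows = df[df["record"] == "vad"]
    if vad_rows.empty:
        raise FormatError(f"{path}: no VAD rows")
    t = pd.to_numeric(vad_rows["t_start_s"], errors="coerce").to_numpy()
    if np.isnan(t).any():
        raise FormatError(f"{path}: non-numeric VAD timestamps")
    hops = np.diff(t)
    if len(hops) and not np.allclose(hops, hops[0], atol=1e-6):
        raise FormatError(f"{path}: non-uniform VAD hop grid")
    hop_s = float(hops[0]) if len(hops) else 0.01
    vad = pd.to_numeric(vad_rows["is_speech"], errors="coerce").fillna(0).to_numpy() > 0
    word_rows = df[df["record"] == "word"]
    words = [
        Word(str(r.token), float(r.onset_s), float(r.offset_s), str(r.speaker))
        for r in word_rows.itertuples()
    ]
    words.sort(key=lambda w: w.onset_s)
    if answer_end_s == np.inf:
        answer_end_s = float(t[-1] + hop_s)
    return SpeechSegment(
        participant_id=participant_id or path.stem,
        segment_index=segment_index,
        vad=vad,
        hop_s=hop_s,
        question_end_s=question_end_s,
        answer_start_s=answer_start_s,
        answer_end_s=answer_end_s,
        words=words,
        t0_s=float(t[0]),
    )


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def read_manifest(path: str | Path, check_files: bool = True) -> list[dict]:
    """Read a cohort manifest and return one record per participant.

    Each record holds id, label, age, sex and the segment entries with file
    paths resolved relative to the manifest's directory. Raises
    :class:`FormatError` for an unknown label or (when ``check_files``) a
    dangling file reference.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    base = path.parent
    records = []
    for part in manifest.get("participants", []):
        pid = part["id"]
        label = part["label"]
        if label not in LABELS:
            raise FormatError(f"participant {pid}: unknown label {label!r}")
        segments = []
        for k, seg in enumerate(part.get("segments", []), start=1):
            entry = dict(seg)
            for key in ("video_csv", "speech_csv"):
                if entry.get(key) is None:
                    continue
                ref = base / entry[key]
                if check_files and not ref.exists():
                    raise FormatError(
                        f"participant {pid} segment {k}: dangling reference {entry[key]}"
                    )
                entry[key] = ref
            entry.setdefault("segment_index", k)
            segments.append(entry)
        records.append(
            {
                "id": pid,
                "label": label,
                "age": part.get("age"),
                "sex": part.get("sex"),
                "segments": segments,
            }
        )
    return records


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the wide per-participant feature table (empty cell = missing)."""
    df = matrix.data.copy()
    df.insert(0, "label", matrix.labels)
    df.index.name = "participant_id"
    df.to_csv(path, float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="participant_id")
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    labels = df["label"]
    data = df.reindex(columns=list(FEATURES)).apply(pd.to_numeric, errors="coerce")
    return FeatureMatrix(data=data, labels=labels)


def write_json_report(report: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=_default)
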