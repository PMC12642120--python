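"""Speech-derived behavioral features from VAD labels and word timestamps.

Three features per answer segment: response latency (ms from the end of the
interviewer's question to the onset of the participant's first word), silence
ratio (proportion of non-speech frames inside the trimmed answer window after
merging sub-150 ms gaps, which are treated as articulation artifacts rather
than pauses), and word count (participant tokens only).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .datamodel import SpeechSegment, Word

MERGE_GAP_MS = 150.0


class SpeechRun(NamedTuple):
    """One merged speech interval on the VAD hop grid."""

    start_s: float
    end_s: float


def merged_speech_labels(
    vad: np.ndarray | Sequence[bool],
    hop_s: float = 0.01,
    merge_ms: float = MERGE_GAP_MS,
) -> np.ndarray:
    """Relabel internal non-speech gaps strictly shorter than ``merge_ms`` as speech.

    Only gaps bounded by speech on both sides are merged; leading and trailing
    silence is untouched. Idempotent.
    """
    vad = np.asarray(vad, dtype=bool)
    if vad.size == 0:
        raise ValueError("empty VAD frame list")
    out = vad.copy()
    n = len(vad)
    i = 0
    while i < n:
        if vad[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not vad[j + 1]:
            j += 1
        gap_ms = (j - i + 1) * hop_s * 1000.0
        if i > 0 and j < n - 1 and gap_ms < merge_ms:
            out[i : j + 1] = True
        i = j + 1
    return out


def merge_speech_gaps(
    vad: np.ndarray | Sequence[bool],
    hop_s: float = 0.01,
    merge_ms: float = MERGE_GAP_MS,
    t0_s: float = 0.0,
) -> list[SpeechRun]:
    """Maximal speech runs after gap merging, ordered and non-overlapping.

    Frame k covers [t0 + k*hop, t0 + (k+1)*hop); a run's end is the end of its
    last frame. Gaps of exactly ``merge_ms`` are kept (strict "< merge_ms").
    """
    merged = merged_speech_labels(vad, hop_s, merge_ms)
    runs: list[SpeechRun] = []
    n = len(merged)
    i = 0
    while i < n:
        if not merged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and merged[j + 1]:
            j += 1
        runs.append(SpeechRun(t0_s + i * hop_s, t0_s + (j + 1) * hop_s))
        i = j + 1
    return runs


def silence_ratio(
    vad: np.ndarray | Sequence[bool],
    answer_window: tuple[float, float],
    hop_s: float = 0.01,
    merge_ms: float = MERGE_GAP_MS,
    t0_s: float = 0.0,
) -> float:
    """Proportion of non-speech frames within the trimmed answer window.

    Gap merging runs on the full series first; frames are then clipped to the
    answer window, and frames before the first merged speech run / after the
    last within the window are excluded (leading/trailing silences lie outside
    the answer proper). Returns NaN when the window contains no speech — the
    trimmed span is undefined.
    """
    merged = merged_speech_labels(vad, hop_s, merge_ms)
    n = len(merged)
    starts = t0_s + np.arange(n) * hop_s
    in_window = (starts >= answer_window[0]) & (starts + hop_s <= answer_window[1] + 1e-12)
    sub = merged[in_window]
    if sub.size == 0 or not sub.any():
        return float("nan")
    speech_idx = np.flatnonzero(sub)
    trimmed = sub[speech_idx[0] : speech_idx[-1] + 1]
    return float((~trimmed).sum() / trimmed.size)


def response_latency(
    question_end_s: float,
    words: Sequence[Word],
    answer_window: tuple[float, float] | None = None,
) -> float:
    """Milliseconds from question end to the participant's first word onset.

    The first participant word (time-ordered, within the answer window when
    one is given) anchors the measurement; an onset preceding the question end
    (speech overlap) clamps the latency to 0. NaN when the participant never
    speaks.
    """
    cand = [w for w in words if w.speaker == "participant"]
    if answer_window is not None:
        cand = [w for w in cand if answer_window[0] <= w.onset_s <= answer_window[1]]
    if not cand:
        return float("nan")
    first = min(cand, key=lambda w: w.onset_s)
    return max(0.0, (first.onset_s - question_end_s) * 1000.0)


def word_count(
    words: Sequence[Word],
    answer_window: tuple[float, float] | None = None,
) -> int:
    """Number of participant tokens (with onset inside the answer window)."""
    count = 0
    for w in words:
        if w.speaker != "participant":
            continue
        if answer_window is not None and not (
            answer_window[0] <= w.onset_s <= answer_window[1]
        ):
            continue
        count += 1
    return count


def extract_speech_features(
    seg: SpeechSegment, merge_ms: float = MERGE_GAP_MS
) -> dict[str, float]:
    """The three speech features of one answer segment (NaN = missing)."""
    return {
        "response_latency_ms": response_latency(
            seg.question_end_s, seg.words, seg.answer_window
        ),
        "silence_ratio": silence_ratio(
            seg.vad, seg.answer_window, seg.hop_s, merge_ms, seg.t0_s
        ),
        "word_count": float(word_count(seg.words, seg.answer_window)),
    }
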