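"""Seeded synthetic-cohort generator with planted ground truth.

Because the study-style raw recordings this pipeline was designed around are
not publicly distributable, the generator emits full synthetic cohorts in the
exact on-disk stream formats the pipeline consumes: per-frame eye landmarks
(constructed so the eye-aspect-ratio of the emitted points reproduces a
planted EAR trace), gaze angles from a semi-Markov left/center/right dwell
process, AU activation traces from planted episode intervals, head pose from
a random walk with planted large jumps, and VAD/word streams from a planted
speech-burst schedule. Every planted event is recorded in a ground-truth log
*before* dropouts are applied, so pipeline output can be scored against known
truth, and group-level effects enter only through interpretable parameters
(center-gaze occupancy, smile-episode rate, blink closed-duration, pause
length), mirroring the directional clinical findings the cohort emulates
(depressed participants: less center gaze, less smiling/Duchenne smiling,
longer blinks, longer pauses).

Default group targets for center gaze are mean 13.51 s (SD 5.75) for the MDD
group versus 19.22 s (SD 3.78) for controls per 30 s segment, with cohort
sizes 44/41 — the study conditions the rest of the pipeline is tested under.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import SegmentStream, SpeechSegment, Word
from . import io as pio

EYE_WIDTH_PX = 30.0  # fixed horizontal landmark span d(p1, p4)


@dataclass
class GroupParams:
    """Interpretable generative parameters for one diagnostic group."""

    # gaze: participant-level center-gaze target (seconds per 30 s segment)
    center_gaze_mean_s: float = 19.22
    center_gaze_sd_s: float = 3.78
    center_dwell_mean_s: float = 3.0
    off_right_share: float = 0.5
    # blinks
    blink_rate_per_min: float = 17.0
    blink_dur_median_s: float = 0.18
    blink_dur_log_sigma: float = 0.35
    open_ear_mean: float = 0.30
    open_ear_sd: float = 0.02
    closed_ear: float = 0.08
    # facial affect (AU12 smile episodes; AU6 co-activation = Duchenne)
    au12_rate_per_min: float = 2.0
    au12_mean_len_s: float = 2.0
    duchenne_p: float = 0.6
    au_other_rate_per_min: float = 2.0
    au_other_mean_len_s: float = 1.0
    # head movement
    head_step_sd_deg: float = 0.3
    jump_rate_per_min: float = 3.0
    jump_min_deg: float = 6.0
    jump_max_deg: float = 10.0
    # speech
    latency_median_s: float = 0.6
    latency_log_sigma: float = 0.5
    burst_mean_s: float = 2.5
    pause_median_s: float = 0.55
    pause_log_sigma: float = 0.45
    words_per_s_mean: float = 2.05
    words_per_s_sd: float = 0.25
    # demographics
    age_mean: float = 37.2
    age_sd: float = 10.0
    female_p: float = 21 / 41


def mdd_params() -> GroupParams:
    """MDD-group defaults: reduced center gaze and positive affect, longer
    blinks and pauses relative to controls."""
    return GroupParams(
        center_gaze_mean_s=13.51,
        center_gaze_sd_s=5.75,
        au12_rate_per_min=1.0,
        au12_mean_len_s=1.6,
        duchenne_p=0.4,
        blink_dur_median_s=0.24,
        pause_median_s=0.75,
        words_per_s_mean=1.95,
        latency_median_s=0.7,
        age_mean=37.8,
        female_p=24 / 44,
    )


def hc_params() -> GroupParams:
    return GroupParams()


@dataclass
class CohortConfig:
    """Cohort-level layout, noise and dropout settings plus the group params."""

    n_mdd: int = 44
    n_hc: int = 41
    fps: float = 30.0
    segments: int = 4
    segment_s: float = 30.0
    hop_s: float = 0.01
    question_end_s: float = 0.8
    # imperfection knobs (all zeroable for the noiseless oracle regime)
    dropout_rate_per_min: float = 1.0  # dropout runs per channel group per minute
    dropout_len_probs: tuple[float, ...] = (0.45, 0.35, 0.15, 0.05)  # len 1..4
    invalid_gaze_rate: float = 0.005  # per-frame planted |yaw| violations
    ear_noise_sd: float = 0.01
    au_noise_sd: float = 0.02
    seed: int = 0
    mdd: GroupParams = field(default_factory=mdd_params)
    hc: GroupParams = field(default_factory=hc_params)

    @property
    def n_frames(self) -> int:
        return int(round(self.segment_s * self.fps))

    def validate(self) -> None:
        gp_list = [("mdd", self.mdd), ("hc", self.hc)]
        for name, gp in gp_list:
            expected_closed = (
                gp.blink_rate_per_min * self.segment_s / 60.0 * gp.blink_dur_median_s * 2.5
            )
            if expected_closed > 0.5 * self.segment_s:
                raise ValueError(
                    f"{name}: blink rate x duration leaves too few open frames"
                )
            if not 0 < gp.center_dwell_mean_s:
                raise ValueError(f"{name}: dwell means must be positive")
            for p in (gp.duchenne_p, gp.off_right_share, gp.female_p):
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}: probabilities must lie in [0, 1]")


def noiseless_config(**overrides) -> CohortConfig:
    """Generator regime with every stochastic imperfection switched off, so
    pipeline output can be compared against planted truth exactly."""
    cfg = CohortConfig(
        dropout_rate_per_min=0.0,
        invalid_gaze_rate=0.0,
        ear_noise_sd=0.0,
        au_noise_sd=0.0,
        **overrides,
    )
    cfg.mdd.head_step_sd_deg = 0.0
    cfg.hc.head_step_sd_deg = 0.0
    return cfg


@dataclass
class ParticipantData:
    participant_id: str
    label: str
    age: float
    sex: str
    streams: list[SegmentStream]
    speech: list[SpeechSegment]
    truth: dict  # per-segment planted ground truth


@dataclass
class SyntheticCohort:
    config: CohortConfig
    participants: list[ParticipantData]

    def ground_truth(self) -> dict:
        return {p.participant_id: p.truth for p in self.participants}


# ---------------------------------------------------------------------------
# per-channel segment generators


def _gen_gaze_segment(
    rng: np.random.Generator, p_center: float, gp: GroupParams, n: int, fps: float,
    invalid_rate: float,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Semi-Markov center/off dwell process; off dwells split left/right.

    Pitch is emitted strictly inside the planted class's angular band; yaw
    stays within the validity bound except at planted invalid frames.
    """
    p = float(np.clip(p_center, 0.02, 0.98))
    mu_c = gp.center_dwell_mean_s
    mu_o = mu_c * (1.0 - p) / p
    pitch = np.empty(n)
    intervals: list[tuple[int, int, str]] = []
    in_center = bool(rng.random() < p)
    t = 0
    while t < n:
        mu = mu_c if in_center else mu_o
        dur = max(1, int(round(rng.exponential(mu) * fps)))
        dur = min(dur, n - t)
        if in_center:
            cls = "center"
            pitch[t : t + dur] = rng.uniform(-0.15, 0.15, size=dur)
        else:
            cls = "right" if rng.random() < gp.off_right_share else "left"
            band = rng.uniform(0.19, 0.34, size=dur)
            pitch[t : t + dur] = band if cls == "right" else -band
        intervals.append((t, t + dur - 1, cls))
        t += dur
        in_center = not in_center
    yaw = rng.uniform(-0.25, 0.25, size=n)
    invalid = rng.random(n) < invalid_rate
    yaw[invalid] = rng.choice([-0.45, 0.45], size=int(invalid.sum()))
    frames_per_class = {
        cls: int(sum(e - s + 1 for s, e, c in intervals if c == cls))
        for cls in ("left", "center", "right")
    }
    truth = {
        "dwell_intervals": intervals,
        "class_frames": frames_per_class,
        "class_s": {k: v / fps for k, v in frames_per_class.items()},
        "invalid_frames": np.flatnonzero(invalid).tolist(),
    }
    return pitch, yaw, truth


def _place_events(
    rng: np.random.Generator, n: int, count: int, lengths: np.ndarray, margin: int
) -> list[tuple[int, int]]:
    """Place non-overlapping closed intervals with ``margin`` open frames
    between events and from the segment boundaries (drops what cannot fit)."""
    events: list[tuple[int, int]] = []
    occupied = np.zeros(n, dtype=bool)
    for length in lengths[:count]:
        length = int(length)
        if length >= n - 2 * margin:
            continue
        for _ in range(20):  # rejection sampling
            start = int(rng.integers(margin, n - margin - length + 1))
            lo = max(0, start - margin)
            hi = min(n, start + length + margin)
            if not occupied[lo:hi].any():
                occupied[start : start + length] = True
                events.append((start, start + length - 1))
                break
    events.sort()
    return events


def _gen_blink_segment(
    rng: np.random.Generator, gp: GroupParams, n: int, fps: float,
    open_ear: float, ear_noise_sd: float,
) -> tuple[np.ndarray, dict]:
    """Planted EAR trace: open baseline with rectangular blink closures."""
    count = rng.poisson(gp.blink_rate_per_min * (n / fps) / 60.0)
    mu = np.log(gp.blink_dur_median_s)
    lengths = np.maximum(
        1, np.round(rng.lognormal(mu, gp.blink_dur_log_sigma, size=count) * fps)
    ).astype(int)
    events = _place_events(rng, n, count, lengths, margin=2)
    ear = np.full(n, open_ear)
    if ear_noise_sd > 0:
        ear += rng.normal(0.0, ear_noise_sd, size=n)
    for s, e in events:
        ear[s : e + 1] = gp.closed_ear
    closed_frames = int(sum(e - s + 1 for s, e in events))
    truth = {
        "blink_events": events,
        "blink_count": len(events),
        "closed_frames": closed_frames,
        "blink_duration_s": (closed_frames / len(events) / fps) if events else 0.0,
        "open_ear": float(open_ear),
    }
    return ear, truth


def landmarks_from_ear(ear: np.ndarray, rng: np.random.Generator | None = None,
                       width: float = EYE_WIDTH_PX) -> np.ndarray:
    """Construct six eye landmarks per frame whose EAR equals the planted trace.

    The horizontal span d(p1,p4) is fixed at ``width`` pixels and both
    vertical lid distances are set to EAR x width, so the canonical ratio
    (v1 + v2) / (2 h) reproduces the trace exactly. A random rigid offset per
    call keeps fixtures from being axis-aligned at the origin.
    """
    n = len(ear)
    v = np.asarray(ear) * width  # each vertical lid distance
    pts = np.empty((n, 6, 2))
    pts[:, 0] = (0.0, 0.0)  # p1 outer corner
    pts[:, 3] = (width, 0.0)  # p4 inner corner
    pts[:, 1, 0] = width / 3.0  # p2 upper lid
    pts[:, 1, 1] = v / 2.0
    pts[:, 5, 0] = width / 3.0  # p6 lower lid (pairs with p2)
    pts[:, 5, 1] = -v / 2.0
    pts[:, 2, 0] = 2.0 * width / 3.0  # p3 upper lid
    pts[:, 2, 1] = v / 2.0
    pts[:, 4, 0] = 2.0 * width / 3.0  # p5 lower lid (pairs with p3)
    pts[:, 4, 1] = -v / 2.0
    if rng is not None:
        offset = rng.uniform(100.0, 800.0, size=2)
        pts += offset
    return pts


def _gen_au_segment(
    rng: np.random.Generator, gp: GroupParams, n: int, fps: float, noise_sd: float
) -> tuple[dict[str, np.ndarray], dict]:
    minutes = (n / fps) / 60.0
    n12 = rng.poisson(gp.au12_rate_per_min * minutes)
    len12 = np.maximum(
        1, np.round(rng.exponential(gp.au12_mean_len_s, size=n12) * fps)
    ).astype(int)
    ep12 = _place_events(rng, n, n12, len12, margin=3)
    duchenne = [bool(rng.random() < gp.duchenne_p) for _ in ep12]
    n_other = rng.poisson(gp.au_other_rate_per_min * minutes)
    len_other = np.maximum(
        1, np.round(rng.exponential(gp.au_other_mean_len_s, size=n_other) * fps)
    ).astype(int)
    ep_other = _place_events(rng, n, n_other, len_other, margin=3)

    def trace(episodes: list[tuple[int, int]], level: float = 0.8) -> np.ndarray:
        arr = np.full(n, 0.05)
        for s, e in episodes:
            arr[s : e + 1] = level
        if noise_sd > 0:
            arr = np.clip(arr + rng.normal(0.0, noise_sd, size=n), 0.0, 1.0)
        return arr

    au12 = trace(ep12)
    au06 = trace([ep for ep, d in zip(ep12, duchenne) if d])
    au_other = trace(ep_other)

    smiling = np.zeros(n, dtype=bool)
    for s, e in ep12:
        smiling[s : e + 1] = True
    happy = np.zeros(n, dtype=bool)
    for (s, e), d in zip(ep12, duchenne):
        if d:
            happy[s : e + 1] = True
    other_active = np.zeros(n, dtype=bool)
    for s, e in ep_other:
        other_active[s : e + 1] = True
    neutral = ~(smiling | happy | other_active)
    truth = {
        "au12_episodes": ep12,
        "duchenne": duchenne,
        "au_other_episodes": ep_other,
        "smiling_frames": int(smiling.sum()),
        "happy_frames": int(happy.sum()),
        "neutral_frames": int(neutral.sum()),
        "smiling_mask": smiling,
    }
    return {"au06": au06, "au12": au12, "au_other_max": au_other}, truth


def _gen_head_segment(
    rng: np.random.Generator, gp: GroupParams, n: int, fps: float
) -> tuple[np.ndarray, dict]:
    steps = rng.normal(0.0, gp.head_step_sd_deg, size=(n - 1, 3))
    n_jumps = rng.poisson(gp.jump_rate_per_min * (n / fps) / 60.0)
    jump_pairs = []
    if n_jumps > 0:
        at = rng.choice(n - 1, size=min(n_jumps, n - 1), replace=False)
        for k in at:
            axis = int(rng.integers(0, 3))
            size = rng.uniform(gp.jump_min_deg, gp.jump_max_deg) * rng.choice([-1, 1])
            steps[k, axis] += size
            jump_pairs.append(int(k))
    pose = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    pose += rng.uniform(-5.0, 5.0, size=3)
    abs_steps = np.abs(steps)
    truth = {
        "total_deg": float(abs_steps.sum()),
        "rapid_pairs": sorted(
            int(k) for k in np.flatnonzero(abs_steps.max(axis=1) > 5.0)
        ),
        "rapid_count": int((abs_steps.max(axis=1) > 5.0).sum()),
        "planted_jump_pairs": sorted(jump_pairs),
    }
    return pose, truth


def _gen_speech_segment(
    rng: np.random.Generator, gp: GroupParams, cfg: CohortConfig,
    pid: str, seg_index: int,
) -> tuple[SpeechSegment, dict]:
    seg_end = cfg.segment_s
    qe = cfg.question_end_s
    latency_s = float(
        np.clip(rng.lognormal(np.log(gp.latency_median_s), gp.latency_log_sigma),
                0.05, 5.0)
    )
    wps = float(np.clip(rng.normal(gp.words_per_s_mean, gp.words_per_s_sd), 0.8, 4.0))
    bursts: list[tuple[float, float]] = []
    words: list[Word] = [
        Word("how", 0.10, 0.25, "interviewer"),
        Word("have", 0.28, 0.42, "interviewer"),
        Word("you-been", 0.45, qe - 0.08, "interviewer"),
    ]
    t = qe + latency_s
    while t < seg_end - 0.35:
        burst = float(np.clip(rng.exponential(gp.burst_mean_s), 0.4, 6.0))
        burst = min(burst, seg_end - 0.05 - t)
        if burst < 0.3:
            break
        n_words = max(1, int(np.floor(burst * wps)))
        spacing = burst / n_words
        for k in range(n_words):
            onset = t + k * spacing
            words.append(Word(f"w{len(words)}", onset, min(onset + 0.8 * spacing, seg_end),
                              "participant"))
        bursts.append((t, t + burst))
        t += burst
        pause = float(np.clip(
            rng.lognormal(np.log(gp.pause_median_s), gp.pause_log_sigma), 0.20, 4.0
        ))
        t += pause
    # hop-grid VAD labels: frame speech iff its midpoint falls in any speech interval
    n_hops = int(round(seg_end / cfg.hop_s))
    mid = (np.arange(n_hops) + 0.5) * cfg.hop_s
    speech_intervals = [(0.08, qe - 0.06)] + bursts  # interviewer question + answer
    vad = np.zeros(n_hops, dtype=bool)
    for s, e in speech_intervals:
        vad |= (mid >= s) & (mid < e)
    n_participant_words = sum(1 for w in words if w.speaker == "participant")
    pauses = [(bursts[i][1], bursts[i + 1][0]) for i in range(len(bursts) - 1)]
    if bursts:
        span = bursts[-1][1] - bursts[0][0]
        pause_time = sum(e - s for s, e in pauses)
        true_silence = pause_time / span if span > 0 else float("nan")
    else:
        true_silence = float("nan")
    seg = SpeechSegment(
        participant_id=pid,
        segment_index=seg_index,
        vad=vad,
        hop_s=cfg.hop_s,
        question_end_s=qe,
        answer_start_s=qe,
        answer_end_s=seg_end,
        words=sorted(words, key=lambda w: w.onset_s),
    )
    truth = {
        "latency_ms": latency_s * 1000.0,
        "word_count": n_participant_words,
        "bursts": bursts,
        "pauses": pauses,
        "silence_ratio": true_silence,
    }
    return seg, truth


def _apply_dropouts(
    rng: np.random.Generator, stream: SegmentStream, cfg: CohortConfig
) -> dict[str, list[tuple[int, int]]]:
    """Plant missing runs per channel group (after ground-truth capture)."""
    n = stream.n_frames
    lens = np.arange(1, len(cfg.dropout_len_probs) + 1)
    planted: dict[str, list[tuple[int, int]]] = {}
    for group in stream.missing:
        runs: list[tuple[int, int]] = []
        count = rng.poisson(cfg.dropout_rate_per_min * (n / stream.fps) / 60.0)
        for _ in range(count):
            length = int(rng.choice(lens, p=cfg.dropout_len_probs))
            start = int(rng.integers(0, n - length + 1))
            stream.missing[group][start : start + length] = True
            runs.append((start, start + length - 1))
        planted[group] = runs
        mask = stream.missing[group]
        if mask.any():
            if group == "eye":
                stream.eye_left[mask] = np.nan
                stream.eye_right[mask] = np.nan
            elif group == "head":
                stream.head_pose[mask] = np.nan
            elif group == "gaze":
                stream.gaze[mask] = np.nan
            else:
                for key in stream.AU_KEYS:
                    stream.au[key][mask] = np.nan
    return planted


def generate_participant(
    seed_seq: np.random.SeedSequence,
    pid: str,
    label: str,
    gp: GroupParams,
    cfg: CohortConfig,
) -> ParticipantData:
    rng = np.random.default_rng(seed_seq)
    n = cfg.n_frames
    fps = cfg.fps
    age = float(np.clip(rng.normal(gp.age_mean, gp.age_sd), 18, 55))
    sex = "F" if rng.random() < gp.female_p else "M"
    # participant-level traits
    p_center = rng.normal(gp.center_gaze_mean_s / cfg.segment_s,
                          gp.center_gaze_sd_s / cfg.segment_s)
    open_ear = float(np.clip(rng.normal(gp.open_ear_mean, gp.open_ear_sd), 0.24, 0.40))
    streams: list[SegmentStream] = []
    speech_segs: list[SpeechSegment] = []
    truth: dict = {"label": label, "segments": []}
    for k in range(1, cfg.segments + 1):
        pitch, yaw, gaze_truth = _gen_gaze_segment(
            rng, p_center, gp, n, fps, cfg.invalid_gaze_rate
        )
        ear, blink_truth = _gen_blink_segment(rng, gp, n, fps, open_ear,
                                              cfg.ear_noise_sd)
        au, au_truth = _gen_au_segment(rng, gp, n, fps, cfg.au_noise_sd)
        pose, head_truth = _gen_head_segment(rng, gp, n, fps)
        speech_seg, speech_truth = _gen_speech_segment(rng, gp, cfg, pid, k)

        center_mask = np.zeros(n, dtype=bool)
        for s, e, cls in gaze_truth["dwell_intervals"]:
            if cls == "center":
                center_mask[s : e + 1] = True
        social_frames = int((au_truth.pop("smiling_mask") & center_mask).sum())

        landmarks = landmarks_from_ear(ear, rng)
        stream = SegmentStream(
            participant_id=pid,
            segment_index=k,
            fps=fps,
            eye_left=landmarks.copy(),
            eye_right=landmarks.copy() + np.array([EYE_WIDTH_PX * 2.0, 0.0]),
            head_pose=pose,
            gaze=np.column_stack([pitch, yaw]),
            au=au,
        )
        dropouts = _apply_dropouts(rng, stream, cfg)
        streams.append(stream)
        speech_segs.append(speech_seg)
        truth["segments"].append(
            {
                "segment_index": k,
                "gaze": gaze_truth,
                "blinks": blink_truth,
                "affect": {**au_truth, "social_frames": social_frames},
                "head": head_truth,
                "speech": speech_truth,
                "dropouts": dropouts,
            }
        )
    return ParticipantData(pid, label, age, sex, streams, speech_segs, truth)


def generate_cohort(cfg: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort; byte-reproducible from the seed."""
    cfg = cfg or CohortConfig()
    cfg.validate()
    master = seed if seed is not None else cfg.seed
    root = np.random.SeedSequence(master)
    n_total = cfg.n_mdd + cfg.n_hc
    children = root.spawn(n_total)
    participants = []
    for i in range(n_total):
        label = "MDD" if i < cfg.n_mdd else "HC"
        gp = cfg.mdd if label == "MDD" else cfg.hc
        pid = f"p{i + 1:03d}"
        participants.append(generate_participant(children[i], pid, label, gp, cfg))
    return SyntheticCohort(config=cfg, participants=participants)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write streams, speech tables, manifest and ground truth to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"fps": cohort.config.fps, "participants": []}
    for part in cohort.participants:
        entry = {
            "id": part.participant_id,
            "label": part.label,
            "age": part.age,
            "sex": part.sex,
            "segments": [],
        }
        for stream, speech in zip(part.streams, part.speech):
            k = stream.segment_index
            video_name = f"{part.participant_id}_s{k}_video.csv"
            speech_name = f"{part.participant_id}_s{k}_speech.csv"
            pio.write_segment_stream(stream, outdir / video_name)
            pio.write_speech_segment(speech, outdir / speech_name)
            entry["segments"].append(
                {
                    "video_csv": video_name,
                    "speech_csv": speech_name,
                    "question_end_s": speech.question_end_s,
                    "answer_start_s": speech.answer_start_s,
                    "answer_end_s": speech.answer_end_s,
                }
            )
        manifest["participants"].append(entry)
    pio.write_manifest(manifest, outdir / "manifest.json")
    truth = {
        p.participant_id: _jsonable(p.truth) for p in cohort.participants
    }
    pio.write_json_report(truth, outdir / "ground_truth.json")
    return outdir / "manifest.json"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# fast feature-level simulation + effect-size calibration


def _simulate_center_gaze(
    rng: np.random.Generator, gp: GroupParams, cfg: CohortConfig, n_participants: int
) -> np.ndarray:
    """Participant-level measured center-gaze seconds without materializing
    frame arrays (dwell arithmetic + binomial thinning for invalid frames)."""
    n = cfg.n_frames
    fps = cfg.fps
    out = np.empty(n_participants)
    for i in range(n_participants):
        p = float(np.clip(
            rng.normal(gp.center_gaze_mean_s / cfg.segment_s,
                       gp.center_gaze_sd_s / cfg.segment_s),
            0.02, 0.98,
        ))
        mu_c = gp.center_dwell_mean_s
        mu_o = mu_c * (1.0 - p) / p
        seg_vals = np.empty(cfg.segments)
        for k in range(cfg.segments):
            t = 0
            center_frames = 0
            in_center = bool(rng.random() < p)
            while t < n:
                mu = mu_c if in_center else mu_o
                dur = max(1, int(round(rng.exponential(mu) * fps)))
                dur = min(dur, n - t)
                if in_center:
                    center_frames += dur
                t += dur
                in_center = not in_center
            if cfg.invalid_gaze_rate > 0 and center_frames > 0:
                center_frames = int(rng.binomial(center_frames,
                                                 1.0 - cfg.invalid_gaze_rate))
            seg_vals[k] = center_frames / fps
        out[i] = seg_vals.mean()
    return out


def _simulate_smiling(
    rng: np.random.Generator, gp: GroupParams, cfg: CohortConfig, n_participants: int
) -> np.ndarray:
    minutes = cfg.segment_s / 60.0
    out = np.empty(n_participants)
    for i in range(n_participants):
        vals = []
        for _ in range(cfg.segments):
            count = rng.poisson(gp.au12_rate_per_min * minutes)
            lens = rng.exponential(gp.au12_mean_len_s, size=count)
            vals.append(min(lens.sum(), 0.8 * cfg.segment_s))
        out[i] = float(np.mean(vals))
    return out


def _simulate_blink_duration(
    rng: np.random.Generator, gp: GroupParams, cfg: CohortConfig, n_participants: int
) -> np.ndarray:
    fps = cfg.fps
    out = np.empty(n_participants)
    for i in range(n_participants):
        vals = []
        for _ in range(cfg.segments):
            count = rng.poisson(gp.blink_rate_per_min * cfg.segment_s / 60.0)
            if count == 0:
                vals.append(0.0)
                continue
            frames = np.maximum(1, np.round(
                rng.lognormal(np.log(gp.blink_dur_median_s),
                              gp.blink_dur_log_sigma, size=count) * fps))
            vals.append(frames.sum() / count / fps)
        out[i] = float(np.mean(vals))
    return out


#: feature -> (monotone GroupParams field, fast participant-level simulator,
#: search bounds for the field)
CALIBRATABLE: dict[str, tuple[str, callable, tuple[float, float]]] = {
    "center_gaze_s": ("center_gaze_mean_s", _simulate_center_gaze, (1.0, 28.5)),
    "smiling_s": ("au12_rate_per_min", _simulate_smiling, (0.05, 20.0)),
    "blink_duration_s": ("blink_dur_median_s", _simulate_blink_duration, (0.05, 1.0)),
}


def calibrate_effect(
    feature: str,
    target_d: float,
    config: CohortConfig | None = None,
    n_cal: int = 2000,
    tol: float = 0.05,
    seed: int = 0,
    max_iter: int = 30,
) -> dict:
    """Bisect a group-B (control) generator parameter to a target Cohen's d.

    The effect is measured as d = (HC mean - MDD mean) / pooled SD on
    simulated participant-level feature values (``n_cal`` per group); the MDD
    group stays fixed and the designated monotone control-group parameter is
    bisected until |d - target| <= ``tol``. Common random numbers across
    iterations keep the search stable. Returns the adjusted parameter value
    and the achieved d.
    """
    if feature not in CALIBRATABLE:
        raise ValueError(
            f"{feature!r} has no designated calibration parameter; "
            f"calibratable: {sorted(CALIBRATABLE)}"
        )
    cfg = config or CohortConfig()
    param, simulate, (lo, hi) = CALIBRATABLE[feature]
    rng_a = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    vals_a = simulate(rng_a, cfg.mdd, cfg, n_cal)

    def d_at(theta: float) -> float:
        gp_b = dataclasses.replace(cfg.hc, **{param: theta})
        rng_b = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        vals_b = simulate(rng_b, gp_b, cfg, n_cal)
        sa, sb = vals_a.std(ddof=1), vals_b.std(ddof=1)
        pooled = np.sqrt(((n_cal - 1) * sa**2 + (n_cal - 1) * sb**2) / (2 * n_cal - 2))
        return float((vals_b.mean() - vals_a.mean()) / pooled)

    d_lo, d_hi = d_at(lo), d_at(hi)
    if not (min(d_lo, d_hi) - tol <= target_d <= max(d_lo, d_hi) + tol):
        raise ValueError(
            f"target d={target_d} unreachable within {param} in [{lo}, {hi}] "
            f"(achievable range [{min(d_lo, d_hi):.2f}, {max(d_lo, d_hi):.2f}])"
        )
    increasing = d_hi >= d_lo
    theta, achieved = None, None
    for _ in range(max_iter):
        theta = 0.5 * (lo + hi)
        achieved = d_at(theta)
        if abs(achieved - target_d) <= tol:
            break
        if (achieved < target_d) == increasing:
            lo = theta
        else:
            hi = theta
    return {"feature": feature, "parameter": param, "value": float(theta),
            "achieved_d": float(achieved), "target_d": float(target_d)}
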