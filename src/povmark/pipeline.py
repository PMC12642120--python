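"""End-to-end orchestration: streams -> features -> QC -> statistics -> ML.

Stage order follows the analysis workflow: per-segment feature extraction,
dropout interpolation and exclusion rules, participant-level aggregation into
the 15-feature matrix, domain-corrected group statistics, and nested-LOOCV
classification. Every report embeds the configuration and seed it was
produced with.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as pio
from .datamodel import FeatureMatrix, SegmentStream, SpeechSegment
from .ml import CVConfig, evaluate_classifier
from .qc import (
    INTERP_MAX_GAP_FRAMES,
    PARTICIPANT_EXCLUDE_AT,
    SEGMENT_EXCLUDE_AT,
    QCReport,
    assemble_matrix,
    interpolate_stream,
    qc_participant,
)
from .speech import MERGE_GAP_MS, extract_speech_features
from .stats import report_table, run_domain_analysis
from .visual import (
    AU_ACTIVE_THRESHOLD,
    EAR_THRESHOLD,
    GAZE_PITCH_THRESHOLD_RAD,
    GAZE_YAW_VALID_RAD,
    RAPID_HEAD_THRESHOLD_DEG,
    extract_visual_features,
)

log = logging.getLogger("povmark")


@dataclass
class PipelineConfig:
    """All tunable thresholds and options, with their standard defaults."""

    interp_max_gap_frames: int = INTERP_MAX_GAP_FRAMES
    segment_exclude_at: float = SEGMENT_EXCLUDE_AT
    participant_exclude_at: float = PARTICIPANT_EXCLUDE_AT
    ear_threshold: float = EAR_THRESHOLD
    gaze_pitch_thr_rad: float = GAZE_PITCH_THRESHOLD_RAD
    gaze_yaw_valid_rad: float = GAZE_YAW_VALID_RAD
    rapid_head_thr_deg: float = RAPID_HEAD_THRESHOLD_DEG
    au_active_thr: float = AU_ACTIVE_THRESHOLD
    merge_gap_ms: float = MERGE_GAP_MS
    family_alpha: float = 0.05
    welch: bool = True
    learner: str = "extra_trees"
    wilson_mode: str = "replicate"
    bootstrap_B: int = 2000
    seed: int = 0
    fps: float = 30.0

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


def extract_participant_features(
    streams: list[SegmentStream],
    speech: list[SpeechSegment | None],
    config: PipelineConfig,
) -> tuple[dict[str, float], dict]:
    """Interpolate, extract and QC one participant's segments."""
    interp_streams = []
    visual_records = []
    for stream in streams:
        cleaned, _ = interpolate_stream(stream, config.interp_max_gap_frames)
        interp_streams.append(cleaned)
        visual_records.append(
            extract_visual_features(
                cleaned,
                ear_threshold=config.ear_threshold,
                au_active_thr=config.au_active_thr,
                pitch_thr=config.gaze_pitch_thr_rad,
                yaw_valid=config.gaze_yaw_valid_rad,
                rapid_thr_deg=config.rapid_head_thr_deg,
            )
        )
    speech_present = [seg is not None for seg in speech]
    speech_records = [
        extract_speech_features(seg, config.merge_gap_ms) if seg is not None else {}
        for seg in speech
    ]
    return qc_participant(
        interp_streams,
        speech_present,
        visual_records,
        speech_records,
        segment_exclude_at=config.segment_exclude_at,
        participant_exclude_at=config.participant_exclude_at,
    )


def extract_cohort(
    participants: list[tuple[str, str, list[SegmentStream], list[SpeechSegment | None]]],
    config: PipelineConfig | None = None,
) -> tuple[FeatureMatrix, QCReport]:
    """Feature matrix + QC report from in-memory participant data.

    ``participants`` holds (id, label, streams, speech segments) tuples.
    """
    config = config or PipelineConfig()
    vectors: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    qc = QCReport()
    for pid, label, streams, speech in participants:
        vector, record = extract_participant_features(streams, speech, config)
        vectors[pid] = vector
        labels[pid] = label
        qc.participants[pid] = record
        for seg in record["segments"]:
            qc.segments[f"{pid}/s{seg['segment_index']}"] = seg
        log.info("QC %s: %d/%d segments kept", pid, record["n_segments_kept"],
                 len(streams))
    return assemble_matrix(vectors, labels), qc


def extract_from_manifest(
    manifest_path: str | Path, config: PipelineConfig | None = None
) -> tuple[FeatureMatrix, QCReport]:
    """Feature matrix + QC report from an on-disk cohort manifest."""
    config = config or PipelineConfig()
    records = pio.read_manifest(manifest_path)
    if not records:
        raise pio.FormatError(f"{manifest_path}: empty manifest")
    participants = []
    for rec in records:
        streams = []
        speech: list[SpeechSegment | None] = []
        for seg in rec["segments"]:
            streams.append(
                pio.read_segment_stream(
                    seg["video_csv"],
                    participant_id=rec["id"],
                    segment_index=seg["segment_index"],
                    fps=config.fps,
                )
            )
            if seg.get("speech_csv") is None:
                speech.append(None)
            else:
                speech.append(
                    pio.read_speech_segment(
                        seg["speech_csv"],
                        participant_id=rec["id"],
                        segment_index=seg["segment_index"],
                        question_end_s=seg.get("question_end_s", 0.0),
                        answer_start_s=seg.get("answer_start_s", 0.0),
                        answer_end_s=seg.get("answer_end_s", np.inf),
                    )
                )
        participants.append((rec["id"], rec["label"], streams, speech))
    return extract_cohort(participants, config)


def run_pipeline(
    manifest_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    cv_config: CVConfig | None = None,
    run_ml: bool = True,
) -> dict:
    """Full run: extraction + QC -> matrix -> group statistics -> classifier.

    Writes the feature matrix CSV, QC report JSON, group-comparison table
    CSV/JSON and (optionally) the classifier metric report JSON to
    ``outdir``; each JSON embeds the configuration for provenance.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config": config.provenance()}

    matrix, qc = extract_from_manifest(manifest_path, config)
    pio.write_feature_matrix(matrix, outdir / "feature_matrix.csv")
    pio.write_json_report(
        {**provenance, **qc.to_dict()}, outdir / "qc_report.json"
    )

    results = run_domain_analysis(
        matrix, qc_report=qc, family_alpha=config.family_alpha, welch=config.welch
    )
    table = report_table(results)
    table.to_csv(outdir / "group_comparisons.csv", index=False)
    stats_json = {
        **provenance,
        "results": [
            {
                "feature": r.feature,
                "domain": r.domain,
                "test": r.test,
                "statistic": r.statistic,
                "df": r.df,
                "u1": r.u_statistic,
                "z": r.z,
                "p": r.p,
                "alpha_domain": r.alpha_domain,
                "tier": r.tier,
                "effect_size": r.effect_size,
                "effect_size_name": r.effect_size_name,
                "direction": r.direction,
            }
            for r in results
        ],
    }
    pio.write_json_report(stats_json, outdir / "group_comparisons.json")

    out = {"matrix": matrix, "qc": qc, "stats": results}
    if run_ml:
        evaluation = evaluate_classifier(
            matrix,
            learner=config.learner,
            config=cv_config,
            seed=config.seed,
            bootstrap_B=config.bootstrap_B,
            wilson_mode=config.wilson_mode,
        )
        pio.write_json_report(
            {**provenance, **_metric_jsonable(evaluation["report"])},
            outdir / "classifier_metrics.json",
        )
        evaluation["predictions"].to_csv(outdir / "pooled_predictions.csv")
        out["ml"] = evaluation
    return out


def _metric_jsonable(report: dict) -> dict:
    out = {}
    for k, v in report.items():
        if isinstance(v, dict):
            out[k] = _metric_jsonable(v)
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out
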