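"""End-to-end single-subject and cohort drivers.

Stage order per subject: band-pass filter -> bad-channel detection and
spherical-spline interpolation -> contaminated-window rejection -> average
reference -> segmentation -> 200 uV epoch rejection -> Welch log-spectra ->
PSD outlier screen -> personalized mu band per baseline -> ERD/ERS table ->
cluster statistics -> classification / baseline preference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess as pp
from .cohort import (
    SubjectResult,
    SubjectTests,
    evaluate_subject,
    subject_tests_from_results,
    summarize_cohort,
)
from .core import AnnotationSet, ChannelLayout, PipelineConfig, Recording
from .erd import ErdTable, HandUsage, compute_erd_table, lateralized_score
from .spectral import MuBand, find_mu_band, outlier_screen, welch_log_psd
from .stats import TestResult, one_sample_family, paired_family
from .synthetic_data import CohortMember

__all__ = ["SubjectAnalysis", "run_cohort", "run_subject"]

logger = logging.getLogger("muerd")


@dataclass
class SubjectAnalysis:
    """Full per-subject output: QC, bands, ERD table, test families and the
    classified result."""

    subject_id: str
    result: SubjectResult
    qc: dict
    bands: dict[str, MuBand] = field(default_factory=dict)
    erd_table: ErdTable | None = None
    onesample: dict[tuple[str, str], list[TestResult]] = field(default_factory=dict)
    paired: dict[str, list[TestResult]] = field(default_factory=dict)
    tests: SubjectTests | None = None

    def write_qc(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.qc, fh, indent=2)


def run_subject(
    rec: Recording,
    ann: AnnotationSet,
    layout: ChannelLayout,
    cfg: PipelineConfig | None = None,
    subject_id: str = "subject",
) -> SubjectAnalysis:
    cfg = cfg or PipelineConfig()
    qc: dict = {"subject": subject_id}

    rec = pp.bandpass_filter(rec, cfg.hp_hz, cfg.lp_hz)
    bad = pp.detect_bad_channels(
        rec,
        flat_s=cfg.flat_s,
        corr_thresh=cfg.corr_thresh,
        corr_window_s=cfg.corr_window_s,
        bad_window_fraction=cfg.corr_bad_fraction,
        max_bad_fraction=cfg.max_bad_fraction,
    )
    qc["interpolated_channels"] = [rec.channel_names[i] for i in bad]
    rec = pp.interpolate_channels(rec, bad)
    rec, keep = pp.reject_contaminated_windows(
        rec, cfg.reject_window_s, cfg.reject_chan_fraction, cfg.amp_thresh_uv
    )
    qc["rejected_seconds"] = float((~keep).sum() / rec.sfreq)
    rec = pp.average_reference(rec)
    es = pp.segment_epochs(rec, ann, keep_mask=keep, cfg=cfg)
    es = pp.reject_artifact_epochs(es, cfg.amp_thresh_uv)
    qc["epoch_counts"] = {c: es.count(c) for c in ("BL2", "AO", "AE")}
    qc["bl1_seconds"] = float(sum(s.shape[1] for s in es.bl1_segments) / es.sfreq)

    lacking = pp.insufficient_conditions(es, cfg.min_epochs_per_condition)
    if lacking:
        logger.warning("%s: insufficient data in %s", subject_id, lacking)
        qc["insufficient_conditions"] = lacking
        return SubjectAnalysis(
            subject_id=subject_id,
            result=SubjectResult(subject_id=subject_id, group="insufficient_data"),
            qc=qc,
        )

    ss = welch_log_psd(es, cfg)
    outliers = outlier_screen(ss, cfg)
    qc["psd_outlier_epochs"] = outliers
    if outliers:
        ss = ss.select([i for i in range(len(ss.conditions)) if i not in outliers])

    bands = {b: find_mu_band(ss, b, cfg) for b in ("BL1", "BL2")}
    qc["mu_band"] = {b: [bands[b].lo, bands[b].hi] for b in bands}
    erd_table = compute_erd_table(ss, bands, layout, cfg)

    onesample = {
        (cond, base): one_sample_family(erd_table.values[(cond, base)], cfg)
        for cond in ("AO", "AE")
        for base in ("BL1", "BL2")
    }
    paired = {
        cond: paired_family(
            erd_table.values[(cond, "BL1")], erd_table.values[(cond, "BL2")], cfg
        )
        for cond in ("AO", "AE")
    }
    n_epochs = {c: erd_table.epoch_count(c) for c in ("AO", "AE")}
    tests = subject_tests_from_results(subject_id, onesample, paired, n_epochs)
    result = evaluate_subject(tests, cfg.alpha)
    hands = [h for h, c in zip(ss.hands, ss.conditions) if c == "AE"]
    usage = HandUsage.from_hands(hands)
    if usage.n_right + usage.n_left:
        result.lateralized_score = lateralized_score(usage)
    result.mu_band_center = {b: bands[b].center for b in bands}

    return SubjectAnalysis(
        subject_id=subject_id,
        result=result,
        qc=qc,
        bands=bands,
        erd_table=erd_table,
        onesample=onesample,
        paired=paired,
        tests=tests,
    )


def run_cohort(
    members: list[CohortMember],
    layout: ChannelLayout,
    cfg: PipelineConfig | None = None,
) -> tuple[list[SubjectAnalysis], "object"]:
    """Run every subject and summarize; returns (analyses, CohortSummary)."""
    analyses = [
        run_subject(m.recording, m.annotations, layout, cfg, m.scenario.subject_id)
        for m in members
    ]
    summary = summarize_cohort([a.result for a in analyses])
    return analyses, summary
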