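"""End-to-end orchestration: curate → time → measure → account.

Streams over exams one at a time (constant memory in cohort size), logs
one structured record per exam, and produces a result table, the
feasibility funnel and — when ground truth is available — Bland–Altman
agreement, deterministically for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .agreement import FunnelReport, bland_altman, feasibility_funnel
from .config import PipelineConfig
from .curation import CurationOutcome, ExclusionReason, curate_exam, get_backend
from .exam_model import ExamRecord
from .measurement import MeasurementExclusion, MeasurementResult, measure_exam
from .synthetic import GroundTruth
from .timing import (DisabledTimingBackend, OracleTimingBackend,
                     TimingUnavailableError, resolve_events)

RESULT_COLUMNS = [
    "study_uid", "edv_ml", "esv_ml", "ef_pct", "la_esv_ml", "bsa_m2",
    "lavi_ml_m2", "dice_ed", "dice_es", "qc_pass", "timing_source",
    "n_clips", "exclusion_reason",
]


def _timing_backend(name: str):
    if name == "oracle":
        return OracleTimingBackend()
    if name == "disabled":
        return DisabledTimingBackend()
    if name == "none":
        return None
    raise KeyError(f"no timing backend named {name!r}")


@dataclass
class PipelineOutput:
    results: pd.DataFrame
    funnel: FunnelReport
    log: List[dict]
    agreement: Optional[dict] = None
    provenance: dict = field(default_factory=dict)


def process_exam(exam: ExamRecord, config: PipelineConfig,
                 modality_backend, view_backend, timing_backend,
                 ) -> Tuple[CurationOutcome, object]:
    """Curate and measure one exam; second element is a
    :class:`MeasurementResult` or :class:`MeasurementExclusion`."""
    outcome = curate_exam(exam, modality_backend, view_backend,
                          config.confidence_threshold)
    if not outcome.included:
        return outcome, MeasurementExclusion(exam.study_uid,
                                             outcome.exclusion_reason.value)

    needed = {rid for ids in outcome.lv_candidates.values() for rid in ids}
    if outcome.la_included:
        needed |= {rid for ids in outcome.la_candidates.values() for rid in ids}
    events: Dict[str, list] = {}
    for rid in needed:
        rec = exam.get_recording(rid)
        try:
            events[rid] = resolve_events(rec, exam.patient, timing_backend,
                                         config.timing_cutoff_frames)
        except TimingUnavailableError:
            events[rid] = []
    if all(not events.get(rid) for ids in outcome.lv_candidates.values()
           for rid in ids):
        return outcome, MeasurementExclusion(exam.study_uid, "timing_unavailable")

    result = measure_exam(exam, outcome, events,
                          dice_threshold=config.dice_threshold,
                          n_discs=config.n_discs,
                          bsa_formula=config.bsa_formula)
    return outcome, result


def run_pipeline(exams: Iterable[ExamRecord], config: PipelineConfig,
                 truths: Optional[Dict[str, GroundTruth]] = None,
                 ) -> PipelineOutput:
    """Run curation + measurement over a cohort and assemble all reports."""
    modality_backend = get_backend("modality", config.modality_backend,
                                   **({"seed": config.seed}
                                      if config.modality_backend == "noisy" else {}))
    view_backend = get_backend("view", config.view_backend,
                               **({"seed": config.seed}
                                  if config.view_backend == "noisy" else {}))
    timing_backend = _timing_backend(config.timing_backend)

    rows: List[dict] = []
    terminal: List[ExclusionReason] = []
    log: List[dict] = []
    for exam in exams:
        outcome, result = process_exam(exam, config, modality_backend,
                                       view_backend, timing_backend)
        if isinstance(result, MeasurementResult):
            reason = ExclusionReason.NONE
            rows.append({
                "study_uid": result.study_uid,
                "edv_ml": result.edv_ml, "esv_ml": result.esv_ml,
                "ef_pct": result.ef_pct, "la_esv_ml": result.la_esv_ml,
                "bsa_m2": result.bsa_m2, "lavi_ml_m2": result.lavi_ml_m2,
                "dice_ed": result.dice_ed, "dice_es": result.dice_es,
                "qc_pass": result.qc_pass,
                "timing_source": result.timing_source,
                "n_clips": result.n_clips_averaged,
                "exclusion_reason": "none",
            })
        else:
            reason = ExclusionReason(result.reason)
            rows.append({"study_uid": exam.study_uid,
                         **{c: None for c in RESULT_COLUMNS[1:-1]},
                         "exclusion_reason": reason.value})
        terminal.append(reason)
        log.append({
            "study_uid": exam.study_uid,
            "included": reason is ExclusionReason.NONE,
            "exclusion_reason": reason.value,
            "quality_class": outcome.quality_class,
        })

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    results = results.sort_values("study_uid", kind="stable").reset_index(drop=True)
    funnel = feasibility_funnel(terminal)

    agreement = None
    if truths:
        measured = results[results.exclusion_reason == "none"]
        auto_ef, ref_ef, auto_lavi, ref_lavi = [], [], [], []
        for _, row in measured.iterrows():
            truth = truths.get(row.study_uid)
            if truth is None:
                continue
            auto_ef.append(row.ef_pct)
            ref_ef.append(truth.ef_pct)
            if row.lavi_ml_m2 is not None and not pd.isna(row.lavi_ml_m2):
                auto_lavi.append(row.lavi_ml_m2)
                ref_lavi.append(truth.lavi_ml_m2)
        agreement = {}
        if len(auto_ef) >= 2:
            agreement["ef"] = bland_altman(auto_ef, ref_ef).as_dict()
        if len(auto_lavi) >= 2:
            agreement["lavi"] = bland_altman(auto_lavi, ref_lavi).as_dict()

    config_hash = hashlib.sha256(
        json.dumps(config.as_dict(), sort_keys=True).encode()).hexdigest()[:12]
    provenance = {"package_version": __version__, "seed": config.seed,
                  "config_hash": config_hash, "config": config.as_dict()}
    return PipelineOutput(results=results, funnel=funnel, log=log,
                          agreement=agreement, provenance=provenance)
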