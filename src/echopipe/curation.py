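"""Exam curation: modality/view classification, QC gates and view selection.

Phase 1 of the pipeline.  Learned classifiers are injected through a small
backend contract (a registry ships an *oracle* backend that reads the
synthetic ground-truth annotations and a *noisy* backend with seeded label
flips for robustness tests); this module owns the label taxonomies, the
confidence gate (view-classification confidence >= 0.85 for inclusion),
image-quality aggregation, the LV-focused/standard view hierarchy, and the
exam-level exclusion accounting that feeds the feasibility funnel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np

from .exam_model import (MODALITY_TAXONOMY, VIEW_TAXONOMY, ExamRecord,
                         Modality, Recording, View)

DEFAULT_CONFIDENCE_THRESHOLD = 0.85

#: slot → acceptable views, most preferred first (LVEF path)
LVEF_VIEW_HIERARCHY: Dict[str, Tuple[View, ...]] = {
    "a4c": (View.A4C_LV_FOCUSED, View.A4C),
    "a2c": (View.A2C_LV_FOCUSED, View.A2C),
}

#: LAVI path uses standard (non-focused) views only
LAVI_VIEW_HIERARCHY: Dict[str, Tuple[View, ...]] = {
    "a4c": (View.A4C,),
    "a2c": (View.A2C,),
}


class ExclusionReason(str, Enum):
    NONE = "none"
    TEE_ONLY = "tee_only"
    NO_BMODE = "no_bmode"
    MISSING_A4C = "missing_A4C"
    MISSING_A2C = "missing_A2C"
    LOW_VIEW_CONFIDENCE = "low_view_confidence"
    MISSING_A4C_FOR_LA = "missing_A4C_for_LA"
    MISSING_A2C_FOR_LA = "missing_A2C_for_LA"
    TIMING_UNAVAILABLE = "timing_unavailable"
    INVALID_SEGMENTATION = "invalid_segmentation"
    LOW_DICE = "low_dice"
    OTHER = "other"


class BackendContractError(ValueError):
    """A classifier backend violated its probability contract."""


class ClassifierBackend(Protocol):
    taxonomy: Tuple[str, ...]

    def classify(self, recording: Recording) -> Tuple[str, np.ndarray]: ...


@dataclass
class ViewSelection:
    """Gated-in recordings filling the A4C and A2C slots of one path."""

    candidates: Dict[str, List[str]]  # slot -> recording ids, best confidence first
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def ok(self) -> bool:
        return self.exclusion_reason is ExclusionReason.NONE

    @property
    def representatives(self) -> Dict[str, str]:
        return {slot: ids[0] for slot, ids in self.candidates.items() if ids}


@dataclass
class CurationOutcome:
    study_uid: str
    included: bool
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    selected_lv_views: Dict[str, str] = field(default_factory=dict)
    lv_candidates: Dict[str, List[str]] = field(default_factory=dict)
    la_included: bool = False
    la_exclusion_reason: ExclusionReason = ExclusionReason.NONE
    selected_la_views: Dict[str, str] = field(default_factory=dict)
    la_candidates: Dict[str, List[str]] = field(default_factory=dict)
    quality_class: Optional[int] = None


def _validate_probs(probs: np.ndarray, taxonomy: Sequence[str]) -> None:
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(taxonomy),):
        raise BackendContractError(
            f"probability vector length {probs.shape} does not match "
            f"taxonomy size {len(taxonomy)}")
    if (probs < 0).any():
        raise BackendContractError("negative probability")
    if abs(float(probs.sum()) - 1.0) > 1e-6:
        raise BackendContractError(f"probabilities sum to {probs.sum():.6f}, not 1")


def classify_modality(recording: Recording,
                      backend: ClassifierBackend) -> Tuple[Modality, float]:
    """Classify the imaging modality and write the label onto the recording.

    Backend contract violations propagate; runtime backend failures mark
    the recording ``unknown`` instead of crashing the exam.
    """
    expected = tuple(m.value for m in MODALITY_TAXONOMY)
    if tuple(backend.taxonomy) != expected:
        raise BackendContractError(
            f"modality backend taxonomy {backend.taxonomy} != {expected}")
    try:
        label, probs = backend.classify(recording)
    except BackendContractError:
        raise
    except Exception:
        recording.modality = Modality.UNKNOWN
        recording.flags.append("modality_backend_failure")
        return Modality.UNKNOWN, 0.0
    _validate_probs(probs, backend.taxonomy)
    modality = Modality(label)
    recording.modality = modality
    return modality, float(np.max(probs))


def classify_view(recording: Recording,
                  backend: ClassifierBackend) -> Tuple[View, float]:
    """Classify the B-mode view; only valid on 2-D B-mode recordings."""
    if recording.modality is not Modality.B2D:
        raise ValueError(
            f"view classification requires B2D modality, got {recording.modality.value}")
    try:
        label, probs = backend.classify(recording)
    except BackendContractError:
        raise
    except Exception:
        recording.view = View.UNKNOWN
        recording.view_confidence = 0.0
        recording.flags.append("view_backend_failure")
        return View.UNKNOWN, 0.0
    _validate_probs(probs, backend.taxonomy)
    view = View(label)
    confidence = float(np.max(probs))
    recording.view = view
    recording.view_confidence = confidence
    return view, confidence


def gate_view_confidence(confidence: float,
                         threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> bool:
    """Inclusion gate on view-classification confidence (>= threshold)."""
    return confidence >= threshold


def aggregate_image_quality(regional_scores: Sequence[float]) -> int:
    """Global 0–5 image-quality class: mean of regional scores, rounded half-up."""
    if len(regional_scores) == 0:
        raise ValueError("regional_scores must be non-empty")
    scores = np.asarray(regional_scores, dtype=float)
    if (scores < 0).any() or (scores > 5).any():
        raise ValueError("regional scores must lie in [0, 5]")
    mean = float(scores.mean())
    return int(min(5, max(0, int(np.floor(mean + 0.5)))))


def _select_views(exam: ExamRecord, hierarchy: Dict[str, Tuple[View, ...]],
                  threshold: float,
                  missing_reasons: Dict[str, ExclusionReason]) -> ViewSelection:
    """Fill each slot from gated-in B2D recordings, preferring early hierarchy views.

    The confidence gate applies first; the preference order then chooses
    among the survivors.  A slot with candidates of the right view but all
    below the gate reports ``low_view_confidence``; a slot with no such
    views at all reports the slot's missing-view reason.
    """
    bmode = [r for r in exam.recordings if r.modality is Modality.B2D]
    candidates: Dict[str, List[str]] = {}
    for slot in ("a4c", "a2c"):
        views = hierarchy[slot]
        chosen: List[Recording] = []
        any_labelled = False
        for view in views:  # most preferred first; stop at first filled tier
            tier = [r for r in bmode if r.view is view]
            any_labelled = any_labelled or bool(tier)
            gated = [r for r in tier if gate_view_confidence(r.view_confidence, threshold)]
            if gated:
                chosen = sorted(gated, key=lambda r: -r.view_confidence)
                break
        if not chosen:
            reason = (ExclusionReason.LOW_VIEW_CONFIDENCE if any_labelled
                      else missing_reasons[slot])
            return ViewSelection(candidates={}, exclusion_reason=reason)
        candidates[slot] = [r.recording_id for r in chosen]
    return ViewSelection(candidates=candidates)


def select_views_for_lvef(exam: ExamRecord,
                          threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> ViewSelection:
    """LVEF path: prefer LV-focused apical views, fall back to standard.

    LV-focused views visualize the ventricle without foreshortening and are
    used when available; each chamber slot falls back to the standard view
    independently.
    """
    if not any(r.modality is Modality.B2D for r in exam.recordings):
        return ViewSelection(candidates={}, exclusion_reason=ExclusionReason.NO_BMODE)
    return _select_views(exam, LVEF_VIEW_HIERARCHY, threshold,
                         {"a4c": ExclusionReason.MISSING_A4C,
                          "a2c": ExclusionReason.MISSING_A2C})


def select_views_for_lavi(exam: ExamRecord,
                          threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> ViewSelection:
    """LAVI path: standard A4C/A2C only (they visualize the full atrium)."""
    if not any(r.modality is Modality.B2D for r in exam.recordings):
        return ViewSelection(candidates={}, exclusion_reason=ExclusionReason.NO_BMODE)
    return _select_views(exam, LAVI_VIEW_HIERARCHY, threshold,
                         {"a4c": ExclusionReason.MISSING_A4C_FOR_LA,
                          "a2c": ExclusionReason.MISSING_A2C_FOR_LA})


def curate_exam(exam: ExamRecord,
                modality_backend: ClassifierBackend,
                view_backend: ClassifierBackend,
                confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> CurationOutcome:
    """Run the full curation chain for one exam.

    Modality classification → view classification of B-mode clips →
    confidence gate → hierarchical view selection, with transoesophageal
    (TEE)-only exams excluded outright.  Exclusions are data, not errors.
    """
    for rec in exam.recordings:
        classify_modality(rec, modality_backend)
        if rec.modality is Modality.B2D:
            classify_view(rec, view_backend)

    bmode = [r for r in exam.recordings if r.modality is Modality.B2D]
    if bmode and all(r.view is View.TEE for r in bmode):
        return CurationOutcome(study_uid=exam.study_uid, included=False,
                               exclusion_reason=ExclusionReason.TEE_ONLY)

    lv = select_views_for_lvef(exam, confidence_threshold)
    la = select_views_for_lavi(exam, confidence_threshold)

    quality_class = None
    scored = [r for r in bmode
              if r.regional_quality and r.recording_id in
              {rid for ids in lv.candidates.values() for rid in ids}]
    if scored:
        pooled = [q for r in scored for q in r.regional_quality]
        quality_class = aggregate_image_quality(pooled)

    return CurationOutcome(
        study_uid=exam.study_uid,
        included=lv.ok,
        exclusion_reason=lv.exclusion_reason,
        selected_lv_views=lv.representatives,
        lv_candidates=lv.candidates,
        la_included=la.ok,
        la_exclusion_reason=la.exclusion_reason,
        selected_la_views=la.representatives,
        la_candidates=la.candidates,
        quality_class=quality_class,
    )


# ---------------------------------------------------------------------------
# Shipped classifier backends

class OracleModalityBackend:
    """Returns the true modality stored in the recording's annotations."""

    taxonomy = tuple(m.value for m in MODALITY_TAXONOMY)

    def classify(self, recording: Recording) -> Tuple[str, np.ndarray]:
        ann = recording.annotations or {}
        label = ann.get("true_modality", recording.modality.value)
        if label not in self.taxonomy:
            label = Modality.B2D.value
        probs = np.zeros(len(self.taxonomy))
        probs[self.taxonomy.index(label)] = 1.0
        return label, probs


class OracleViewBackend:
    """Returns the true view, honouring any injected confidence override."""

    taxonomy = tuple(v.value for v in VIEW_TAXONOMY)

    def classify(self, recording: Recording) -> Tuple[str, np.ndarray]:
        ann = recording.annotations or {}
        label = ann.get("true_view", recording.view.value)
        confidence = float(ann.get("confidence_override", 1.0))
        n = len(self.taxonomy)
        probs = np.full(n, (1.0 - confidence) / (n - 1))
        probs[self.taxonomy.index(label)] = confidence
        return label, probs


class NoisyBackend:
    """Seeded label-flip wrapper around an oracle backend, for stress tests."""

    def __init__(self, inner, flip_rate: float = 0.05, seed: int = 0,
                 confidence_jitter: float = 0.05):
        self.inner = inner
        self.taxonomy = inner.taxonomy
        self.flip_rate = flip_rate
        self.jitter = confidence_jitter
        self.rng = np.random.default_rng(seed)

    def classify(self, recording: Recording) -> Tuple[str, np.ndarray]:
        label, probs = self.inner.classify(recording)
        if self.rng.random() < self.flip_rate:
            others = [t for t in self.taxonomy if t != label]
            label = others[self.rng.integers(len(others))]
        confidence = float(np.clip(
            np.max(probs) - self.rng.uniform(0, self.jitter), 1e-6, 1.0))
        n = len(self.taxonomy)
        out = np.full(n, (1.0 - confidence) / (n - 1))
        out[self.taxonomy.index(label)] = confidence
        return label, out


BACKEND_REGISTRY = {
    ("modality", "oracle"): OracleModalityBackend,
    ("view", "oracle"): OracleViewBackend,
}


def get_backend(kind: str, name: str, **kwargs):
    """Instantiate a registered classifier backend.

    ``name="noisy"`` wraps the oracle of the same kind; trained models can
    be registered under new names without touching the pipeline.
    """
    if name == "noisy":
        inner = BACKEND_REGISTRY[(kind, "oracle")]()
        return NoisyBackend(inner, **kwargs)
    try:
        return BACKEND_REGISTRY[(kind, name)](**kwargs)
    except KeyError:
        raise KeyError(f"no {kind} backend named {name!r}") from None
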