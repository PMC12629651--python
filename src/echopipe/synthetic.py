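"""Synthetic echocardiographic exams with analytic ground truth.

The phantom left ventricle is a full prolate ellipsoid whose semi-axes
breathe between an end-diastolic and an end-systolic state (cosine
interpolation of the volume), so the exact analytic volumes at ED and ES
equal the requested EDV/ESV.  The A4C and A2C "views" are the two
orthogonal long-axis planes through the ellipsoid — elliptical
cross-sections rasterized at the requested pixel spacing — for which the
biplane method of disks has the closed-form limit V = (π/6)·L·D1·D2.  The
left atrium is an analogous, rounder ellipsoid with known end-systolic
volume.  ES frames are placed with the same sex-specific heart-rate
regression the timing fallback uses, so the two timing sources agree by
construction unless a corruption says otherwise.

Controlled corruptions (dropped views, low classifier confidence, degraded
secondary segmentations, disabled timing output) exercise every exclusion
path of the curation and QC gates with known expected outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .curation import DEFAULT_CONFIDENCE_THRESHOLD, ExclusionReason
from .exam_model import (ExamRecord, MaskStack, Modality, PatientInfo,
                         Recording, Sex, View)
from .measurement import DEFAULT_DICE_THRESHOLD, body_surface_area, dice
from .timing import regression_es_offset

#: views generated for a pristine phantom exam
DEFAULT_VIEWS = (View.A4C_LV_FOCUSED, View.A2C_LV_FOCUSED, View.A4C, View.A2C)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic exam."""

    edv_ml: float = 150.0
    esv_ml: float = 75.0
    la_esv_ml: float = 60.0
    heart_rate: float = 60.0
    frame_rate: float = 50.0
    n_cycles: int = 1
    pixel_spacing: float = 0.5
    sex: Sex = Sex.MALE
    height_cm: float = 175.0
    weight_kg: float = 75.0
    seed: int = 0
    lv_axis_ratio: float = 1.8  # long-axis / short-axis diameter ratio
    la_axis_ratio: float = 1.3
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if not (0 < self.esv_ml < self.edv_ml):
            raise ValueError(f"need 0 < ESV < EDV, got {self.esv_ml}, {self.edv_ml}")
        if self.la_esv_ml <= 0:
            raise ValueError("la_esv_ml must be positive")
        if self.frame_rate < 20:
            raise ValueError("frame_rate must be >= 20 Hz")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")


@dataclass
class CorruptionSpec:
    """Controlled defects injected into a phantom exam.

    ``dice_degradation`` d perturbs the secondary segmentation toward a
    target Dice of 1−d against the primary (achieved value recorded in the
    ground truth).  ``confidence_override`` feeds the oracle view
    classifier.  ``timing_offset_frames`` biases the network events to
    exercise the reconciliation cutoff.
    """

    drop_views: frozenset = frozenset()
    confidence_override: Dict[View, float] = field(default_factory=dict)
    dice_degradation: float = 0.0
    disable_timing_network: bool = False
    timing_offset_frames: int = 0
    quality_scores: Optional[List[float]] = None

    def __post_init__(self) -> None:
        self.drop_views = frozenset(View(v) for v in self.drop_views)
        self.confidence_override = {View(k): float(v)
                                    for k, v in self.confidence_override.items()}
        for v, c in self.confidence_override.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"confidence override {c} for {v} not in [0,1]")
        if not (0.0 <= self.dice_degradation <= 1.0):
            raise ValueError("dice_degradation must lie in [0, 1]")
        if self.quality_scores is not None:
            if any(not (0 <= q <= 5) for q in self.quality_scores):
                raise ValueError("quality scores must lie in [0, 5]")


@dataclass
class GroundTruth:
    """Exact analytic quantities of a generated exam."""

    study_uid: str
    edv_ml: float
    esv_ml: float
    ef_pct: float
    la_esv_ml: float
    bsa_m2: float
    lavi_ml_m2: float
    ed_frames: List[int]
    es_frames: List[int]
    achieved_dice: Optional[float] = None
    expected_exclusion: Optional[str] = None  # ExclusionReason value or None


# ---------------------------------------------------------------------------
# Analytic geometry

def prolate_semi_axes(volume_ml: float, axis_ratio: float) -> Tuple[float, float]:
    """Semi-axes (a, b) in mm of a prolate ellipsoid (b = c) with the given
    volume (mL) and long/short *diameter* ratio a/b."""
    volume_mm3 = volume_ml * 1000.0
    b = (3.0 * volume_mm3 / (4.0 * math.pi * axis_ratio)) ** (1.0 / 3.0)
    return axis_ratio * b, b


def ellipse_mask(shape: Tuple[int, int], center_rc: Tuple[float, float],
                 semi_axes_mm: Tuple[float, float], pixel_spacing: float,
                 angle_deg: float = 0.0) -> np.ndarray:
    """Rasterize an ellipse: pixel centers inside the analytic boundary.

    ``semi_axes_mm[0]`` lies along the (possibly rotated) row axis.
    """
    rows = (np.arange(shape[0]) - center_rc[0]) * pixel_spacing
    cols = (np.arange(shape[1]) - center_rc[1]) * pixel_spacing
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    theta = math.radians(angle_deg)
    u = rr * math.cos(theta) + cc * math.sin(theta)
    v = -rr * math.sin(theta) + cc * math.cos(theta)
    a, b = semi_axes_mm
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _cycle_volume(frame: int, ed_frames: Sequence[int], cycle_ends: Sequence[int],
                  es_offset: int, edv: float, esv: float) -> float:
    """Instantaneous LV volume: cosine systole then cosine diastole."""
    for ed, end in zip(ed_frames, cycle_ends):
        if ed <= frame < end or (frame == end and end == cycle_ends[-1]):
            es = ed + es_offset
            if frame <= es:
                s = (frame - ed) / max(es - ed, 1)
                return edv + (esv - edv) * (1.0 - math.cos(math.pi * min(s, 1.0))) / 2.0
            s = (frame - es) / max(end - es, 1)
            return esv + (edv - esv) * (1.0 - math.cos(math.pi * min(s, 1.0))) / 2.0
    return edv


def _degrade_mask(primary: np.ndarray, target_dice: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Erode or dilate the mask until its Dice against the original drops
    to (at or just below) ``target_dice``."""
    op = ndimage.binary_erosion if rng.random() < 0.5 else ndimage.binary_dilation
    out = primary.copy()
    for _ in range(200):
        if dice(primary, out) <= target_dice:
            break
        out = op(out)
        if not out.any():
            break
    return out


# ---------------------------------------------------------------------------
# Exam generation

def _expected_exclusion(corruption: CorruptionSpec,
                        confidence_threshold: float,
                        dice_threshold: float) -> Optional[str]:
    """The exclusion reason this corruption forces, for funnel accounting."""
    present = set(DEFAULT_VIEWS) - set(corruption.drop_views)
    for slot_views, missing in (
            ({View.A4C_LV_FOCUSED, View.A4C}, ExclusionReason.MISSING_A4C),
            ({View.A2C_LV_FOCUSED, View.A2C}, ExclusionReason.MISSING_A2C)):
        slot_present = slot_views & present
        if not slot_present:
            return missing.value
        gated = [v for v in slot_present
                 if corruption.confidence_override.get(v, 1.0) >= confidence_threshold]
        if not gated:
            return ExclusionReason.LOW_VIEW_CONFIDENCE.value
    if corruption.dice_degradation > 0 and \
            1.0 - corruption.dice_degradation < dice_threshold:
        return ExclusionReason.LOW_DICE.value
    return None


def generate_exam(spec: PhantomSpec,
                  corruption: Optional[CorruptionSpec] = None,
                  study_uid: Optional[str] = None) -> Tuple[ExamRecord, GroundTruth]:
    """Build one synthetic exam and its exact ground truth.

    Four B-mode recordings are generated (LV-focused and standard A4C/A2C;
    LV masks on all, LA masks on the standard views at ES frames) plus one
    PW-Doppler clip that must be filtered out by modality classification.
    Masks are rasterized at the ED and ES frames of every cycle.
    """
    corruption = corruption or CorruptionSpec()
    unknown = corruption.drop_views - set(DEFAULT_VIEWS)
    unknown |= set(corruption.confidence_override) - set(DEFAULT_VIEWS)
    if unknown:
        raise ValueError(f"corruption references views not generated: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    study_uid = study_uid or f"study-{spec.seed:08d}"

    # --- timing layout ------------------------------------------------
    frames_per_cycle = spec.frame_rate * 60.0 / spec.heart_rate
    offset_ms = regression_es_offset(spec.sex, spec.heart_rate)
    es_offset = int(math.floor(offset_ms * spec.frame_rate / 1000.0 + 0.5))
    if es_offset < 1 or es_offset >= frames_per_cycle:
        raise ValueError("ES offset does not fit inside one cardiac cycle")
    ed_frames = [int(round(k * frames_per_cycle)) for k in range(spec.n_cycles)]
    cycle_ends = [int(round((k + 1) * frames_per_cycle)) for k in range(spec.n_cycles)]
    es_frames = [ed + es_offset for ed in ed_frames]
    n_frames = cycle_ends[-1] + 1

    # --- geometry -----------------------------------------------------
    a0, b0 = prolate_semi_axes(spec.edv_ml, spec.lv_axis_ratio)
    la_a, la_b = prolate_semi_axes(spec.la_esv_ml, spec.la_axis_ratio)
    sp = spec.pixel_spacing
    margin = 3.0 * sp + 2.0
    half_h = a0 + margin
    half_w = max(b0, la_b) + margin
    shape = (2 * int(math.ceil(half_h / sp)) + 1,
             2 * int(math.ceil(half_w / sp)) + 1)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    event_frames = sorted(set(ed_frames) | set(es_frames))
    target_dice = 1.0 - corruption.dice_degradation
    achieved_dice: Optional[float] = None

    def lv_stacks() -> Tuple[MaskStack, MaskStack, Optional[float]]:
        prim: Dict[int, np.ndarray] = {}
        sec: Dict[int, np.ndarray] = {}
        worst = None
        for f in event_frames:
            vol = _cycle_volume(f, ed_frames, cycle_ends, es_offset,
                                spec.edv_ml, spec.esv_ml)
            k = (vol / spec.edv_ml) ** (1.0 / 3.0)
            mask = ellipse_mask(shape, center, (k * a0, k * b0), sp,
                                spec.rotation_deg)
            prim[f] = mask
            if corruption.dice_degradation > 0:
                m2 = _degrade_mask(mask, target_dice, rng)
                d = dice(mask, m2)
                worst = d if worst is None else min(worst, d)
                sec[f] = m2
            else:
                sec[f] = mask.copy()
        return MaskStack(prim), MaskStack(sec), worst

    def la_stacks() -> Tuple[MaskStack, MaskStack]:
        prim = {f: ellipse_mask(shape, center, (la_a, la_b), sp, spec.rotation_deg)
                for f in es_frames}
        sec = {f: m.copy() for f, m in prim.items()}
        return MaskStack(prim), MaskStack(sec)

    recordings: List[Recording] = []
    for i, view in enumerate(DEFAULT_VIEWS):
        if view in corruption.drop_views:
            continue
        lv1, lv2, worst = lv_stacks()
        if worst is not None:
            achieved_dice = worst if achieved_dice is None else min(achieved_dice, worst)
        la1 = la2 = None
        if view in (View.A4C, View.A2C):
            la1, la2 = la_stacks()
        ann: Dict[str, object] = {
            "true_modality": Modality.B2D.value,
            "true_view": view.value,
        }
        if view in corruption.confidence_override:
            ann["confidence_override"] = corruption.confidence_override[view]
        if not corruption.disable_timing_network:
            off = corruption.timing_offset_frames
            net_ed = [min(max(f + off, 0), n_frames - 2) for f in ed_frames]
            net_es = [min(max(f + off, net_ed[j] + 1), n_frames - 1)
                      for j, f in enumerate(es_frames)]
            ann["ed_frames"] = net_ed
            ann["es_frames"] = net_es
        recordings.append(Recording(
            recording_id=f"{study_uid}-r{i}-{view.value}",
            frame_rate=spec.frame_rate,
            n_frames=n_frames,
            heart_rate=spec.heart_rate,
            pixel_spacing=sp,
            masks_primary=lv1,
            masks_secondary=lv2,
            la_masks_primary=la1,
            la_masks_secondary=la2,
            ecg_ed_anchors=list(ed_frames),
            regional_quality=(list(corruption.quality_scores)
                              if corruption.quality_scores is not None else None),
            annotations=ann,
        ))

    recordings.append(Recording(
        recording_id=f"{study_uid}-doppler",
        frame_rate=spec.frame_rate,
        n_frames=n_frames,
        heart_rate=spec.heart_rate,
        annotations={"true_modality": Modality.PW_DOPPLER.value},
    ))

    patient = PatientInfo(patient_id=f"pat-{study_uid}", sex=spec.sex,
                          height_cm=spec.height_cm, weight_kg=spec.weight_kg)
    exam = ExamRecord(study_uid=study_uid, patient=patient, recordings=recordings)

    bsa = body_surface_area(spec.weight_kg, spec.height_cm)
    truth = GroundTruth(
        study_uid=study_uid,
        edv_ml=spec.edv_ml,
        esv_ml=spec.esv_ml,
        ef_pct=(spec.edv_ml - spec.esv_ml) / spec.edv_ml * 100.0,
        la_esv_ml=spec.la_esv_ml,
        bsa_m2=bsa,
        lavi_ml_m2=spec.la_esv_ml / bsa,
        ed_frames=list(ed_frames),
        es_frames=list(es_frames),
        achieved_dice=achieved_dice,
        expected_exclusion=_expected_exclusion(
            corruption, DEFAULT_CONFIDENCE_THRESHOLD, DEFAULT_DICE_THRESHOLD),
    )
    return exam, truth


# ---------------------------------------------------------------------------
# Cohort generation

#: realistic sampling ranges for a mixed clinical cohort
DEFAULT_PARAM_RANGES: Dict[str, Tuple[float, float]] = {
    "edv_ml": (90.0, 180.0),
    "ef_pct": (30.0, 65.0),
    "la_esv_ml": (30.0, 90.0),
    "heart_rate": (55.0, 95.0),
    "frame_rate": (40.0, 60.0),
    "height_cm": (150.0, 195.0),
    "weight_kg": (50.0, 110.0),
    "pixel_spacing": (0.5, 0.5),
}


def _draw_spec(rng: np.random.Generator, ranges: Dict[str, Tuple[float, float]],
               seed: int) -> PhantomSpec:
    def u(key: str) -> float:
        lo, hi = ranges[key]
        if hi < lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    edv = u("edv_ml")
    ef = u("ef_pct")
    return PhantomSpec(
        edv_ml=edv,
        esv_ml=edv * (1.0 - ef / 100.0),
        la_esv_ml=u("la_esv_ml"),
        heart_rate=u("heart_rate"),
        frame_rate=u("frame_rate"),
        pixel_spacing=u("pixel_spacing"),
        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        height_cm=u("height_cm"),
        weight_kg=u("weight_kg"),
        seed=seed,
    )


def generate_cohort(n: int, seed: int,
                    param_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
                    corruptions: Optional[Sequence[Tuple[CorruptionSpec, float]]] = None,
                    corruption_mode: str = "counts",
                    ) -> List[Tuple[ExamRecord, GroundTruth]]:
    """Generate ``n`` exams, reproducibly from a single integer seed.

    ``corruptions`` pairs each :class:`CorruptionSpec` with either an exact
    exam count (``corruption_mode="counts"``; assignment order is a seeded
    shuffle) or an independent probability (``"probs"``; the probabilities
    partition the unit interval, so each exam receives at most one
    corruption).  Remaining exams are pristine.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)

    assigned: List[Optional[CorruptionSpec]] = [None] * n
    if corruptions:
        if corruption_mode == "counts":
            pool: List[Optional[CorruptionSpec]] = []
            for cspec, count in corruptions:
                pool.extend([cspec] * int(count))
            if len(pool) > n:
                raise ValueError("corruption counts exceed cohort size")
            pool.extend([None] * (n - len(pool)))
            order = rng.permutation(n)
            assigned = [pool[i] for i in order]
        elif corruption_mode == "probs":
            cum = np.cumsum([p for _, p in corruptions])
            if cum[-1] > 1.0 + 1e-9:
                raise ValueError("corruption probabilities sum above 1")
            for i in range(n):
                u = rng.random()
                idx = int(np.searchsorted(cum, u, side="right"))
                if idx < len(corruptions):
                    assigned[i] = corruptions[idx][0]
        else:
            raise ValueError(f"unknown corruption_mode {corruption_mode!r}")

    cohort: List[Tuple[ExamRecord, GroundTruth]] = []
    for i in range(n):
        spec = _draw_spec(rng, ranges, seed=int(rng.integers(0, 2**31 - 1)))
        cohort.append(generate_exam(spec, assigned[i],
                                    study_uid=f"study-{seed}-{i:04d}"))
    return cohort
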