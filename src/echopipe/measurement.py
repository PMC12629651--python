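"""Biplane Simpson volumetry, Dice-based segmentation QC and derived indices.

The geometric core of the pipeline: given binary LV (or LA) segmentation
masks from two orthogonal apical views (A4C / A2C), volumes are computed
with the method of disks (biplane Simpson),

    V = (pi/4) * (L / n) * sum_i a_i * b_i,

where ``a_i``/``b_i`` are disc diameters perpendicular to each view's long
axis and ``L`` is the common long-axis length (the longer of the two
views, the standard convention).  Ejection fraction, body surface area
(Mosteller) and the left atrial volume index follow from the volumes.

Dual-model segmentation agreement (Dice >= 0.8 between the masks of two
independently trained segmentation models) is the quality gate for
including a clip's measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exam_model import ExamRecord, MaskStack, PatientInfo, Recording
from .timing import CardiacEvents

DEFAULT_DICE_THRESHOLD = 0.8
DEFAULT_N_DISCS = 20
MIN_MASK_PIXELS = 50


class InvalidSegmentationError(ValueError):
    """A mask is unusable for measurement (empty, tiny or fragmented)."""


@dataclass
class LongAxis:
    """Long axis of a chamber mask, from apex to base, in pixel coords."""

    apex_point: Tuple[float, float]
    base_midpoint: Tuple[float, float]
    length_mm: float

    @property
    def length_px(self) -> float:
        dr = self.base_midpoint[0] - self.apex_point[0]
        dc = self.base_midpoint[1] - self.apex_point[1]
        return math.hypot(dr, dc)


@dataclass
class BiplaneVolume:
    n_discs: int
    diameters_a: List[float]
    diameters_b: List[float]
    length_mm: float
    volume_ml: float
    foreshortening_suspected: bool = False


@dataclass
class MeasurementResult:
    study_uid: str
    edv_ml: float
    esv_ml: float
    ef_pct: float
    bsa_m2: float
    la_esv_ml: Optional[float] = None
    lavi_ml_m2: Optional[float] = None
    dice_ed: float = 1.0
    dice_es: float = 1.0
    qc_pass: bool = True
    n_clips_averaged: int = 1
    timing_source: str = "network"


@dataclass
class MeasurementExclusion:
    study_uid: str
    reason: str  # timing_unavailable | invalid_segmentation | low_dice
    detail: str = ""


# ---------------------------------------------------------------------------
# Elementary statistics and indices

def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def segmentation_qc(primary: np.ndarray, secondary: np.ndarray,
                    threshold: float = DEFAULT_DICE_THRESHOLD) -> Tuple[bool, float]:
    """Dual-model agreement gate: pass iff Dice(primary, secondary) >= threshold."""
    d = dice(primary, secondary)
    return d >= threshold, d


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """EF = (EDV − ESV) / EDV · 100, in percent."""
    if edv_ml <= 0:
        raise ValueError(f"EDV must be positive, got {edv_ml}")
    return (edv_ml - esv_ml) / edv_ml * 100.0


def body_surface_area(weight_kg: float, height_cm: float,
                      formula: str = "mosteller") -> float:
    """Body surface area in m².

    Default is the Mosteller formula sqrt(weight·height)/60 (weight in kg,
    height in cm), the usual echo-lab convention; DuBois is available as an
    alternative.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    if formula == "mosteller":
        return math.sqrt(weight_kg * height_cm) / 60.0
    if formula == "dubois":
        return 0.007184 * weight_kg ** 0.425 * height_cm ** 0.725
    raise ValueError(f"unknown BSA formula {formula!r}")


def lavi(la_esv_ml: float, bsa_m2: float) -> float:
    """Left atrial volume index: LA end-systolic volume / BSA, mL/m²."""
    if bsa_m2 <= 0:
        raise ValueError(f"BSA must be positive, got {bsa_m2}")
    return la_esv_ml / bsa_m2


# ---------------------------------------------------------------------------
# Long-axis extraction and disc geometry

def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit vector of the principal (largest-variance) axis of pixel coords."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)
    return eigvecs[:, int(np.argmax(eigvals))]


def _axis_width_profile(ax_coord: np.ndarray, perp_coord: np.ndarray,
                        lo: float, hi: float) -> float:
    """Mean perpendicular extent (px) of pixels with axial coord in [lo, hi]."""
    sel = (ax_coord >= lo) & (ax_coord <= hi)
    if not sel.any():
        return 0.0
    return float(perp_coord[sel].max() - perp_coord[sel].min()) + 1.0


def extract_long_axis(mask: np.ndarray, pixel_spacing: float) -> LongAxis:
    """Locate the chamber long axis via second-order image moments.

    The axis direction is the principal eigenvector of the pixel covariance;
    its endpoints are the extreme projections of mask pixels onto that line
    (extended by half a pixel each to account for the pixel footprint).  The
    *base* end is the endpoint whose neighbourhood (nearest 10% of the axis
    length) has the larger perpendicular width — the mitral annulus plane is
    wider than the apex; ties break toward the endpoint with the larger row
    coordinate.

    Raises :class:`InvalidSegmentationError` for empty, tiny (< 50 px) or
    disconnected masks; these count as segmentation failures upstream.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < MIN_MASK_PIXELS:
        raise InvalidSegmentationError(f"mask has only {n_px} px (< {MIN_MASK_PIXELS})")
    _, n_components = ndimage.label(mask)
    if n_components != 1:
        raise InvalidSegmentationError(f"mask has {n_components} connected components")

    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    u = _principal_axis(coords)
    perp = np.array([-u[1], u[0]])
    ax_coord = (coords - centroid) @ u
    perp_coord = (coords - centroid) @ perp

    lo, hi = float(ax_coord.min()), float(ax_coord.max())
    length_px = (hi - lo) + 1.0  # pixel footprint
    band = 0.1 * (hi - lo)
    width_lo = _axis_width_profile(ax_coord, perp_coord, lo, lo + band)
    width_hi = _axis_width_profile(ax_coord, perp_coord, hi - band, hi)

    end_lo = centroid + (lo - 0.5) * u
    end_hi = centroid + (hi + 0.5) * u
    if width_hi > width_lo:
        base, apex = end_hi, end_lo
    elif width_lo > width_hi:
        base, apex = end_lo, end_hi
    else:  # symmetric phantom; pick the lower-on-screen end as base
        base, apex = (end_hi, end_lo) if end_hi[0] >= end_lo[0] else (end_lo, end_hi)

    return LongAxis(
        apex_point=(float(apex[0]), float(apex[1])),
        base_midpoint=(float(base[0]), float(base[1])),
        length_mm=length_px * pixel_spacing,
    )


def disc_diameters(mask: np.ndarray, axis: LongAxis, pixel_spacing: float,
                   n_discs: int = DEFAULT_N_DISCS) -> List[float]:
    """Chamber diameters at the centers of ``n_discs`` equal slabs.

    The apex→base axis is split into equal slabs; at each slab center the
    mask is sampled along the perpendicular line (bilinear interpolation at
    quarter-pixel steps) and the diameter is the extent between the first
    and last supra-threshold samples, in mm.  Slabs outside the mask give 0.
    """
    mask = np.asarray(mask, dtype=float)
    apex = np.array(axis.apex_point)
    base = np.array(axis.base_midpoint)
    axis_vec = base - apex
    axis_len = np.linalg.norm(axis_vec)
    if axis_len == 0:
        raise ValueError("degenerate axis")
    u = axis_vec / axis_len
    perp = np.array([-u[1], u[0]])

    # sample far enough out to cover any plausible chamber width
    half_extent = max(mask.shape) * 0.75
    step = 0.25
    offsets = np.arange(-half_extent, half_extent + step, step)

    diameters: List[float] = []
    for i in range(n_discs):
        center = apex + (i + 0.5) / n_discs * axis_vec
        pts = center[None, :] + offsets[:, None] * perp[None, :]
        vals = ndimage.map_coordinates(mask, pts.T, order=1, mode="constant", cval=0.0)
        inside = np.flatnonzero(vals >= 0.5)
        if inside.size == 0:
            diameters.append(0.0)
        else:
            extent_px = offsets[inside[-1]] - offsets[inside[0]]
            diameters.append(extent_px * pixel_spacing)
    return diameters


def biplane_simpson(mask_v1: np.ndarray, mask_v2: np.ndarray,
                    spacing_v1: float, spacing_v2: float,
                    n_discs: int = DEFAULT_N_DISCS) -> BiplaneVolume:
    """Biplane method-of-disks volume from two orthogonal view masks, in mL.

    ``L`` is the longer of the two view long-axis lengths.  A length
    discrepancy above 20% flags foreshortening suspicion on the result
    (warning only, never rejection).
    """
    axis1 = extract_long_axis(mask_v1, spacing_v1)
    axis2 = extract_long_axis(mask_v2, spacing_v2)
    d1 = disc_diameters(mask_v1, axis1, spacing_v1, n_discs)
    d2 = disc_diameters(mask_v2, axis2, spacing_v2, n_discs)

    length = max(axis1.length_mm, axis2.length_mm)
    shorter = min(axis1.length_mm, axis2.length_mm)
    foreshortened = (length - shorter) / length > 0.20

    volume_mm3 = (math.pi / 4.0) * (length / n_discs) * float(
        np.dot(d1, d2))
    return BiplaneVolume(
        n_discs=n_discs,
        diameters_a=d1,
        diameters_b=d2,
        length_mm=length,
        volume_ml=volume_mm3 / 1000.0,
        foreshortening_suspected=foreshortened,
    )


# ---------------------------------------------------------------------------
# Exam-level measurement

def _qc_frame(rec: Recording, frame: int, structure: str,
              threshold: float) -> Tuple[bool, float, Optional[np.ndarray]]:
    """QC one frame of one structure; returns (pass, dice, primary mask)."""
    prim_stack = rec.masks_primary if structure == "lv" else rec.la_masks_primary
    sec_stack = rec.masks_secondary if structure == "lv" else rec.la_masks_secondary
    prim = prim_stack.get(frame) if prim_stack else None
    if prim is None:
        return False, float("nan"), None
    sec = sec_stack.get(frame) if sec_stack else None
    if sec is None:
        return True, 1.0, prim  # single-model path: no agreement gate possible
    ok, d = segmentation_qc(prim, sec, threshold)
    return ok, d, prim


def _clip_pair_measurements(rec_a4c: Recording, rec_a2c: Recording,
                            events_a4c: Sequence[CardiacEvents],
                            events_a2c: Sequence[CardiacEvents],
                            dice_threshold: float,
                            n_discs: int) -> Tuple[List[dict], Optional[str]]:
    """Per-cycle LV volumes for one A4C/A2C clip pairing.

    Cycle j of one view is paired with cycle j of the other.  Returns the
    list of per-cycle measurement dicts and, when the list is empty, the
    reason the pairing produced nothing.
    """
    out: List[dict] = []
    failure: Optional[str] = None
    n_cycles = min(len(events_a4c), len(events_a2c))
    if n_cycles == 0:
        return out, "timing_unavailable"
    for j in range(n_cycles):
        ev4, ev2 = events_a4c[j], events_a2c[j]
        frames = {"ed": (ev4.ed_frame, ev2.ed_frame), "es": (ev4.es_frame, ev2.es_frame)}
        masks: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        dices: Dict[str, float] = {}
        ok_all = True
        for phase, (f4, f2) in frames.items():
            ok4, d4, m4 = _qc_frame(rec_a4c, f4, "lv", dice_threshold)
            ok2, d2, m2 = _qc_frame(rec_a2c, f2, "lv", dice_threshold)
            if m4 is None or m2 is None:
                failure = failure or "invalid_segmentation"
                ok_all = False
                break
            dices[phase] = min(d4, d2)
            if not (ok4 and ok2):
                failure = failure or "low_dice"
                ok_all = False
                break
            masks[phase] = (m4, m2)
        if not ok_all:
            continue
        try:
            edv = biplane_simpson(masks["ed"][0], masks["ed"][1],
                                  rec_a4c.pixel_spacing, rec_a2c.pixel_spacing,
                                  n_discs)
            esv = biplane_simpson(masks["es"][0], masks["es"][1],
                                  rec_a4c.pixel_spacing, rec_a2c.pixel_spacing,
                                  n_discs)
        except InvalidSegmentationError:
            failure = failure or "invalid_segmentation"
            continue
        out.append({
            "edv": edv.volume_ml,
            "esv": esv.volume_ml,
            "ef": ejection_fraction(edv.volume_ml, esv.volume_ml),
            "dice_ed": dices["ed"],
            "dice_es": dices["es"],
            "source": "network" if (ev4.source == "network" and ev2.source == "network")
                      else "ecg_regression",
        })
    return out, (failure if not out else None)


def _la_volume(rec_a4c: Recording, rec_a2c: Recording,
               events_a4c: Sequence[CardiacEvents],
               events_a2c: Sequence[CardiacEvents],
               dice_threshold: float, n_discs: int) -> Optional[float]:
    """Mean LA end-systolic biplane volume over paired cycles, or None."""
    vols: List[float] = []
    for j in range(min(len(events_a4c), len(events_a2c))):
        f4, f2 = events_a4c[j].es_frame, events_a2c[j].es_frame
        ok4, _, m4 = _qc_frame(rec_a4c, f4, "la", dice_threshold)
        ok2, _, m2 = _qc_frame(rec_a2c, f2, "la", dice_threshold)
        if m4 is None or m2 is None or not (ok4 and ok2):
            continue
        try:
            vol = biplane_simpson(m4, m2, rec_a4c.pixel_spacing,
                                  rec_a2c.pixel_spacing, n_discs)
        except InvalidSegmentationError:
            continue
        vols.append(vol.volume_ml)
    return float(np.mean(vols)) if vols else None


def measure_exam(exam: ExamRecord, curation, events_by_recording: Dict[str, List[CardiacEvents]],
                 dice_threshold: float = DEFAULT_DICE_THRESHOLD,
                 n_discs: int = DEFAULT_N_DISCS,
                 bsa_formula: str = "mosteller"):
    """Measure EDV/ESV/EF (and LAVI when available) for a curated exam.

    Every gated-in A4C clip is paired with every gated-in A2C clip; within
    each pairing, cycle j is matched with cycle j.  Measurements are
    averaged over cycles within a pairing, then over pairings
    (``n_clips_averaged`` counts pairings that produced at least one valid
    cycle).  Any-stage failure returns a :class:`MeasurementExclusion`
    carrying the funnel reason.
    """
    if not curation.included:
        return MeasurementExclusion(exam.study_uid, curation.exclusion_reason.value)

    a4c_ids = curation.lv_candidates["a4c"]
    a2c_ids = curation.lv_candidates["a2c"]
    per_pair: List[dict] = []
    failures: List[str] = []
    for id4 in a4c_ids:
        for id2 in a2c_ids:
            rec4, rec2 = exam.get_recording(id4), exam.get_recording(id2)
            ev4 = events_by_recording.get(id4, [])
            ev2 = events_by_recording.get(id2, [])
            cycles, failure = _clip_pair_measurements(
                rec4, rec2, ev4, ev2, dice_threshold, n_discs)
            if cycles:
                per_pair.append({
                    "edv": float(np.mean([c["edv"] for c in cycles])),
                    "esv": float(np.mean([c["esv"] for c in cycles])),
                    "ef": float(np.mean([c["ef"] for c in cycles])),
                    "dice_ed": min(c["dice_ed"] for c in cycles),
                    "dice_es": min(c["dice_es"] for c in cycles),
                    "source": ("network" if all(c["source"] == "network" for c in cycles)
                               else "ecg_regression"),
                })
            elif failure:
                failures.append(failure)

    if not per_pair:
        # precedence mirrors the pipeline order: timing, then segmentation, then QC
        for reason in ("timing_unavailable", "invalid_segmentation", "low_dice"):
            if reason in failures:
                return MeasurementExclusion(exam.study_uid, reason)
        return MeasurementExclusion(exam.study_uid, "invalid_segmentation")

    edv = float(np.mean([p["edv"] for p in per_pair]))
    esv = float(np.mean([p["esv"] for p in per_pair]))
    ef = float(np.mean([p["ef"] for p in per_pair]))
    bsa = body_surface_area(exam.patient.weight_kg, exam.patient.height_cm, bsa_formula)

    la_esv = None
    if curation.la_included:
        la4 = curation.la_candidates["a4c"]
        la2 = curation.la_candidates["a2c"]
        la_vols = []
        for id4 in la4:
            for id2 in la2:
                v = _la_volume(exam.get_recording(id4), exam.get_recording(id2),
                               events_by_recording.get(id4, []),
                               events_by_recording.get(id2, []),
                               dice_threshold, n_discs)
                if v is not None:
                    la_vols.append(v)
        if la_vols:
            la_esv = float(np.mean(la_vols))

    return MeasurementResult(
        study_uid=exam.study_uid,
        edv_ml=edv,
        esv_ml=esv,
        ef_pct=ef,
        bsa_m2=bsa,
        la_esv_ml=la_esv,
        lavi_ml_m2=lavi(la_esv, bsa) if la_esv is not None else None,
        dice_ed=min(p["dice_ed"] for p in per_pair),
        dice_es=min(p["dice_es"] for p in per_pair),
        qc_pass=True,
        n_clips_averaged=len(per_pair),
        timing_source=("network" if all(p["source"] == "network" for p in per_pair)
                       else "ecg_regression"),
    )
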