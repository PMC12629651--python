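"""Exam/recording data model and manifest I/O.

An *exam* (one echocardiographic study, keyed by its DICOM Study Instance
UID) contains many *recordings* (clips) of different ultrasound modalities
and B-mode views.  This module defines the validated in-memory containers
every other stage of the pipeline consumes, plus a JSON manifest format for
reading and writing whole exams, with per-frame binary segmentation masks
stored either as external 8-bit PNG files (0/255) or as inline row-major
run-length encodings.

Mask coordinate convention: row-major arrays, origin at the top-left,
0-based indices, isotropic pixel spacing in mm/px stored per recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np

SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """Raised when a manifest or domain object violates an invariant.

    Carries a dotted ``location`` naming the offending exam/recording/field.
    """

    def __init__(self, location: str, message: str):
        self.location = location
        super().__init__(f"{location}: {message}")


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Modality(str, Enum):
    """The eight echocardiographic imaging modalities, plus ``unknown``."""

    B2D = "B2D"
    B3D = "B3D"
    COLOR_FLOW = "color_flow"
    M_MODE = "m_mode"
    PW_DOPPLER = "pw_doppler"
    CW_DOPPLER = "cw_doppler"
    CONTRAST = "contrast"
    TISSUE_DOPPLER = "tissue_doppler"
    UNKNOWN = "unknown"


#: The taxonomy a modality classifier must emit (``unknown`` is reserved
#: for unclassified/failed recordings and is not part of the taxonomy).
MODALITY_TAXONOMY = tuple(m for m in Modality if m is not Modality.UNKNOWN)


class View(str, Enum):
    """Extended B-mode view taxonomy, including LV-focused apical variants."""

    PLAX = "PLAX"
    PLAX_FOCUSED = "PLAX_focused"
    PSAX = "PSAX"
    A4C = "A4C"
    A4C_LV_FOCUSED = "A4C_LV_focused"
    A2C = "A2C"
    A2C_LV_FOCUSED = "A2C_LV_focused"
    ALAX = "ALAX"
    A5C = "A5C"
    SC4C = "SC4C"
    SCVC = "SCVC"
    TEE = "TEE"
    UNKNOWN = "unknown"


VIEW_TAXONOMY = tuple(View)


@dataclass
class PatientInfo:
    """Patient attributes needed for BSA and the sex-specific ES timing."""

    patient_id: str
    sex: Sex
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if not (30.0 < self.height_cm < 260.0):
            raise ValidationError(
                f"patient[{self.patient_id}].height_cm",
                f"height {self.height_cm} cm outside plausible range (30, 260)",
            )
        if not (1.0 < self.weight_kg < 400.0):
            raise ValidationError(
                f"patient[{self.patient_id}].weight_kg",
                f"weight {self.weight_kg} kg outside plausible range (1, 400)",
            )


@dataclass
class MaskStack:
    """A sparse stack of per-frame binary masks on a common grid.

    Only the frames that carry a mask are stored (keyed by 0-based frame
    index); volumetric measurement needs masks at ED/ES frames only.
    """

    frames: Dict[int, np.ndarray]

    def __post_init__(self) -> None:
        shapes = set()
        for idx, arr in self.frames.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValidationError(f"mask[{idx}]", "mask must be 2-D")
            self.frames[idx] = arr.astype(bool)
            shapes.add(arr.shape)
        if len(shapes) > 1:
            raise ValidationError("mask", f"inconsistent grid shapes {shapes}")

    @property
    def shape(self) -> Optional[tuple]:
        if not self.frames:
            return None
        return next(iter(self.frames.values())).shape

    @property
    def frame_indices(self) -> List[int]:
        return sorted(self.frames)

    def get(self, frame: int) -> Optional[np.ndarray]:
        return self.frames.get(frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskStack):
            return NotImplemented
        if set(self.frames) != set(other.frames):
            return False
        return all(np.array_equal(self.frames[i], other.frames[i]) for i in self.frames)


@dataclass
class Recording:
    """One clip: modality/view labels, acquisition metadata and masks.

    ``masks_primary``/``masks_secondary`` hold the dual LV segmentations
    (two independent models; their Dice agreement is the segmentation QC
    metric).  ``la_masks_primary``/``la_masks_secondary`` hold the left
    atrium analogues on the same grid.  ``ecg_ed_anchors`` are the
    cycle-start (end-diastole) frame indices from the ECG annotation.
    ``annotations`` is an optional free-form dict used by oracle backends
    on synthetic data (true modality/view, true event frames).
    """

    recording_id: str
    modality: Modality = Modality.UNKNOWN
    view: View = View.UNKNOWN
    view_confidence: float = 0.0
    frame_rate: Optional[float] = None
    n_frames: int = 1
    heart_rate: Optional[float] = None
    pixel_spacing: Optional[float] = None
    masks_primary: Optional[MaskStack] = None
    masks_secondary: Optional[MaskStack] = None
    la_masks_primary: Optional[MaskStack] = None
    la_masks_secondary: Optional[MaskStack] = None
    ecg_ed_anchors: List[int] = field(default_factory=list)
    regional_quality: Optional[List[float]] = None
    annotations: Optional[Dict[str, Any]] = None
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        loc = f"recording[{self.recording_id}]"
        self.modality = Modality(self.modality)
        self.view = View(self.view)
        if not (0.0 <= self.view_confidence <= 1.0):
            raise ValidationError(f"{loc}.view_confidence",
                                  f"{self.view_confidence} not in [0, 1]")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise ValidationError(f"{loc}.frame_rate",
                                  f"{self.frame_rate} Hz not positive")
        if self.n_frames < 1:
            raise ValidationError(f"{loc}.n_frames", f"{self.n_frames} < 1")
        if self.heart_rate is not None and self.heart_rate <= 0:
            raise ValidationError(f"{loc}.heart_rate",
                                  f"{self.heart_rate} bpm not positive")
        if self.pixel_spacing is not None and self.pixel_spacing <= 0:
            raise ValidationError(f"{loc}.pixel_spacing",
                                  f"{self.pixel_spacing} mm/px not positive")
        if self.regional_quality is not None:
            for i, q in enumerate(self.regional_quality):
                if not (0.0 <= q <= 5.0):
                    raise ValidationError(f"{loc}.regional_quality[{i}]",
                                          f"{q} not in [0, 5]")
        for anchor in self.ecg_ed_anchors:
            if not (0 <= anchor < self.n_frames):
                raise ValidationError(f"{loc}.ecg_ed_anchors",
                                      f"anchor {anchor} outside [0, {self.n_frames})")
        self._check_stacks(loc)

    def _check_stacks(self, loc: str) -> None:
        pairs = [("masks", self.masks_primary, self.masks_secondary),
                 ("la_masks", self.la_masks_primary, self.la_masks_secondary)]
        shapes = set()
        for name, prim, sec in pairs:
            for stack in (prim, sec):
                if stack is not None and stack.shape is not None:
                    shapes.add(stack.shape)
                    if max(stack.frame_indices, default=-1) >= self.n_frames:
                        raise ValidationError(
                            f"{loc}.{name}",
                            "mask frame index beyond n_frames")
            if prim is not None and sec is not None:
                if set(prim.frames) != set(sec.frames):
                    raise ValidationError(
                        f"{loc}.{name}",
                        "primary and secondary stacks cover different frames")
        if len(shapes) > 1:
            raise ValidationError(f"{loc}.masks",
                                  f"mask stacks on different grids: {shapes}")
        if shapes and self.pixel_spacing is None:
            raise ValidationError(f"{loc}.pixel_spacing",
                                  "masks present but pixel_spacing missing")

    @property
    def has_masks(self) -> bool:
        return self.masks_primary is not None and bool(self.masks_primary.frames)


@dataclass
class ExamRecord:
    """One exam: a Study-Instance-UID, patient attributes and recordings."""

    study_uid: str
    patient: PatientInfo
    recordings: List[Recording] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.study_uid:
            raise ValidationError("study_uid", "must be non-empty")
        seen: set = set()
        for rec in self.recordings:
            if rec.recording_id in seen:
                raise ValidationError(
                    f"exam[{self.study_uid}]",
                    f"duplicate recording_id {rec.recording_id!r}")
            seen.add(rec.recording_id)

    def get_recording(self, recording_id: str) -> Recording:
        for rec in self.recordings:
            if rec.recording_id == recording_id:
                return rec
        raise KeyError(recording_id)


# ---------------------------------------------------------------------------
# Run-length encoding (row-major, zeros first) for inline mask storage.

def rle_encode(mask: np.ndarray) -> List[int]:
    """Encode a 2-D boolean mask as alternating run lengths, zeros first."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat.view(np.int8)))
    bounds = np.concatenate(([0], changes + 1, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return runs


def rle_decode(runs: Sequence[int], shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`rle_encode`."""
    total = int(np.prod(shape))
    flat = np.zeros(total, dtype=bool)
    pos = 0
    val = False
    for run in runs:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    if pos != total:
        raise ValidationError("rle", f"run lengths sum to {pos}, expected {total}")
    return flat.reshape(tuple(shape))


# ---------------------------------------------------------------------------
# Manifest (de)serialization

def _stack_to_json(stack: Optional[MaskStack], base: Path, rel: str,
                   mask_format: str) -> Optional[dict]:
    if stack is None:
        return None
    shape = stack.shape
    out: Dict[str, Any] = {"shape": list(shape) if shape else None, "frames": {}}
    for idx in stack.frame_indices:
        mask = stack.frames[idx]
        if mask_format == "rle":
            out["frames"][str(idx)] = {"rle": rle_encode(mask)}
        elif mask_format == "png":
            from PIL import Image

            rel_path = f"{rel}_f{idx:04d}.png"
            path = base / rel_path
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray((mask.astype(np.uint8)) * 255).save(path)
            out["frames"][str(idx)] = {"png": rel_path}
        else:
            raise ValueError(f"unknown mask_format {mask_format!r}")
    return out


def _stack_from_json(obj: Optional[dict], base: Path, loc: str) -> Optional[MaskStack]:
    if obj is None:
        return None
    shape = obj.get("shape")
    frames: Dict[int, np.ndarray] = {}
    for key, entry in obj.get("frames", {}).items():
        idx = int(key)
        if "rle" in entry:
            if shape is None:
                raise ValidationError(loc, "RLE mask without shape")
            frames[idx] = rle_decode(entry["rle"], shape)
        elif "png" in entry:
            from PIL import Image

            path = base / entry["png"]
            if not path.exists():
                raise ValidationError(loc, f"mask file not found: {path}")
            arr = np.asarray(Image.open(path))
            if arr.ndim == 3:
                arr = arr[..., 0]
            frames[idx] = arr > 127
        else:
            raise ValidationError(loc, f"mask frame {idx} has no rle/png payload")
    return MaskStack(frames=frames)


def _recording_to_json(rec: Recording, base: Path, exam_dir: str,
                       mask_format: str) -> dict:
    rel = f"{exam_dir}/{rec.recording_id}"
    return {
        "recording_id": rec.recording_id,
        "modality": rec.modality.value,
        "view": rec.view.value,
        "view_confidence": rec.view_confidence,
        "frame_rate": rec.frame_rate,
        "n_frames": rec.n_frames,
        "heart_rate": rec.heart_rate,
        "pixel_spacing": rec.pixel_spacing,
        "ecg_ed_anchors": list(rec.ecg_ed_anchors),
        "regional_quality": rec.regional_quality,
        "annotations": rec.annotations,
        "flags": list(rec.flags),
        "masks_primary": _stack_to_json(rec.masks_primary, base, rel + "_lv1", mask_format),
        "masks_secondary": _stack_to_json(rec.masks_secondary, base, rel + "_lv2", mask_format),
        "la_masks_primary": _stack_to_json(rec.la_masks_primary, base, rel + "_la1", mask_format),
        "la_masks_secondary": _stack_to_json(rec.la_masks_secondary, base, rel + "_la2", mask_format),
    }


def _recording_from_json(obj: dict, base: Path, loc: str) -> Recording:
    try:
        return Recording(
            recording_id=obj["recording_id"],
            modality=Modality(obj.get("modality", "unknown")),
            view=View(obj.get("view", "unknown")),
            view_confidence=float(obj.get("view_confidence", 0.0)),
            frame_rate=obj.get("frame_rate"),
            n_frames=int(obj.get("n_frames", 1)),
            heart_rate=obj.get("heart_rate"),
            pixel_spacing=obj.get("pixel_spacing"),
            masks_primary=_stack_from_json(obj.get("masks_primary"), base, loc),
            masks_secondary=_stack_from_json(obj.get("masks_secondary"), base, loc),
            la_masks_primary=_stack_from_json(obj.get("la_masks_primary"), base, loc),
            la_masks_secondary=_stack_from_json(obj.get("la_masks_secondary"), base, loc),
            ecg_ed_anchors=[int(a) for a in obj.get("ecg_ed_anchors", [])],
            regional_quality=obj.get("regional_quality"),
            annotations=obj.get("annotations"),
            flags=list(obj.get("flags", [])),
        )
    except KeyError as exc:
        raise ValidationError(loc, f"missing required field {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ValidationError(loc, str(exc)) from exc


def write_manifest(exams: List[ExamRecord], path: Path | str,
                   mask_format: str = "rle") -> None:
    """Write exams to a JSON manifest at ``path``.

    With ``mask_format="png"`` masks go to sibling PNG files referenced by
    relative path; with ``"rle"`` (default) they are inlined as run-length
    encodings, keeping the manifest a single self-contained text file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent
    doc = {
        "schema_version": SCHEMA_VERSION,
        "exams": [
            {
                "study_uid": exam.study_uid,
                "patient": {
                    "patient_id": exam.patient.patient_id,
                    "sex": exam.patient.sex.value,
                    "height_cm": exam.patient.height_cm,
                    "weight_kg": exam.patient.weight_kg,
                },
                "recordings": [
                    _recording_to_json(rec, base, f"masks/{exam.study_uid}", mask_format)
                    for rec in exam.recordings
                ],
            }
            for exam in exams
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_manifest(path: Path | str) -> List[ExamRecord]:
    """Read and fully validate a JSON manifest; returns the exam list.

    Every type invariant is checked; violations raise
    :class:`ValidationError` naming the offending exam/recording and field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError("schema_version",
                              f"unsupported version {doc.get('schema_version')!r}")
    base = path.parent
    exams: List[ExamRecord] = []
    for i, exam_obj in enumerate(doc.get("exams", [])):
        loc = f"exams[{i}]"
        try:
            pat = exam_obj["patient"]
            patient = PatientInfo(
                patient_id=pat["patient_id"],
                sex=Sex(pat["sex"]),
                height_cm=float(pat["height_cm"]),
                weight_kg=float(pat["weight_kg"]),
            )
            recordings = [
                _recording_from_json(rec_obj, base, f"{loc}.recordings[{j}]")
                for j, rec_obj in enumerate(exam_obj.get("recordings", []))
            ]
            exams.append(ExamRecord(
                study_uid=exam_obj["study_uid"],
                patient=patient,
                recordings=recordings,
            ))
        except KeyError as exc:
            raise ValidationError(loc, f"missing required field {exc}") from exc
    return exams


# ---------------------------------------------------------------------------
# DICOM ingestion (public tags only)

def ingest_dicom_metadata(path: Path | str) -> Recording:
    """Extract recording metadata from a standard Part-10 DICOM file.

    Reads public tags only: study UID, frame count, frame rate (from
    FrameTime, CineRate or RecommendedDisplayFrameRate) and heart rate.
    Modality and view are left ``unknown`` for downstream classification.
    A missing frame-rate attribute flags the recording rather than raising.
    """
    import pydicom

    path = Path(path)
    try:
        ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    except Exception as exc:
        raise ValidationError(str(path), f"not a parseable DICOM file: {exc}") from exc

    frame_rate: Optional[float] = None
    if getattr(ds, "FrameTime", None):
        ft = float(ds.FrameTime)
        if ft > 0:
            frame_rate = 1000.0 / ft
    if frame_rate is None and getattr(ds, "CineRate", None):
        frame_rate = float(ds.CineRate)
    if frame_rate is None and getattr(ds, "RecommendedDisplayFrameRate", None):
        frame_rate = float(ds.RecommendedDisplayFrameRate)

    heart_rate = None
    if getattr(ds, "HeartRate", None):
        heart_rate = float(ds.HeartRate)

    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    study_uid = str(getattr(ds, "StudyInstanceUID", ""))
    sop_uid = str(getattr(ds, "SOPInstanceUID", path.stem))

    rec = Recording(
        recording_id=sop_uid,
        modality=Modality.UNKNOWN,
        view=View.UNKNOWN,
        frame_rate=frame_rate,
        n_frames=n_frames,
        heart_rate=heart_rate,
        annotations={"study_uid": study_uid} if study_uid else None,
    )
    if frame_rate is None:
        rec.flags.append("missing_frame_rate")
    return rec
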