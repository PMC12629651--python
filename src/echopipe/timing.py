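"""Cardiac event timing: ED/ES frame detection with ECG-regression fallback.

End-diastole (mitral valve closure) and end-systole (aortic valve closure)
frames are normally provided by a learned event-detection model (a
pluggable backend here).  When that model fails, or disagrees with the
ECG-based regression by more than a predefined cutoff (default five
frames), the pipeline falls back to the regression estimate

    ES = ED + 498 − 1.60 · HR   (male)
    ES = ED + 522 − 1.77 · HR   (female)

with ED/ES in milliseconds and HR the heart rate in beats per minute from
the ECG trace.  The ED anchor itself comes from the cycle-start annotation
(ECG trigger); the regression only places ES relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Protocol, Sequence, Tuple

from .exam_model import PatientInfo, Recording, Sex

DEFAULT_CUTOFF_FRAMES = 5.0

#: intercept (ms) and slope (ms per bpm) of the ES-offset regression
ES_REGRESSION = {
    Sex.MALE: (498.0, 1.6),
    Sex.FEMALE: (522.0, 1.77),
}


class TimingUnavailableError(ValueError):
    """No timing source can place ED/ES for this recording."""


@dataclass
class CardiacEvents:
    """ED and ES frame indices for one cardiac cycle, with provenance."""

    ed_frame: int
    es_frame: int
    source: str  # "network" | "ecg_regression"
    deviation_frames: Optional[float] = None

    def __post_init__(self) -> None:
        if self.es_frame <= self.ed_frame:
            raise ValueError(
                f"es_frame {self.es_frame} must exceed ed_frame {self.ed_frame}")


class EventDetectionBackend(Protocol):
    """Contract for learned ED/ES detectors.

    ``detect`` returns one (ed_frame, es_frame) pair per identified cycle,
    or ``None`` when the model fails to produce a valid output.
    """

    def detect(self, recording: Recording) -> Optional[List[Tuple[int, int]]]: ...


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def regression_es_offset(sex: Sex, heart_rate: float) -> float:
    """ES−ED interval in ms from the sex-specific heart-rate regression."""
    sex = Sex(sex)
    intercept, slope = ES_REGRESSION[sex]
    offset = intercept - slope * heart_rate
    if offset <= 0:
        raise ValueError(
            f"regression offset non-positive ({offset:.1f} ms) at HR {heart_rate}")
    return offset


def ecg_events(recording: Recording, patient: PatientInfo,
               anchor: Optional[int] = None) -> CardiacEvents:
    """Place ES relative to an ED anchor using the ECG regression.

    ``anchor`` defaults to the recording's first ECG cycle-start frame.
    The millisecond offset is converted to frames with round-half-up.
    """
    if recording.heart_rate is None:
        raise TimingUnavailableError(
            f"recording {recording.recording_id}: heart rate absent")
    if recording.frame_rate is None:
        raise TimingUnavailableError(
            f"recording {recording.recording_id}: frame rate absent")
    if anchor is None:
        if not recording.ecg_ed_anchors:
            raise TimingUnavailableError(
                f"recording {recording.recording_id}: no ED anchor annotation")
        anchor = recording.ecg_ed_anchors[0]
    offset_ms = regression_es_offset(patient.sex, recording.heart_rate)
    es = anchor + _round_half_up(offset_ms * recording.frame_rate / 1000.0)
    if es >= recording.n_frames:
        raise TimingUnavailableError(
            f"recording {recording.recording_id}: regression ES frame {es} "
            f"beyond clip length {recording.n_frames}")
    return CardiacEvents(ed_frame=anchor, es_frame=es, source="ecg_regression")


def ecg_events_all_cycles(recording: Recording,
                          patient: PatientInfo) -> List[CardiacEvents]:
    """ECG-regression events for every annotated cycle that fits the clip."""
    events = []
    for anchor in recording.ecg_ed_anchors:
        try:
            events.append(ecg_events(recording, patient, anchor))
        except TimingUnavailableError:
            continue
    if not events:
        raise TimingUnavailableError(
            f"recording {recording.recording_id}: no usable ECG cycle")
    return events


def detect_events(recording: Recording,
                  backend: Optional[EventDetectionBackend]) -> Optional[List[CardiacEvents]]:
    """Run the learned event detector; backend failure degrades to ``None``."""
    if backend is None:
        return None
    try:
        pairs = backend.detect(recording)
    except Exception:
        return None
    if pairs is None:
        return None
    events = []
    for ed, es in pairs:
        if not (0 <= ed < es < recording.n_frames):
            return None
        events.append(CardiacEvents(ed_frame=ed, es_frame=es, source="network"))
    return events or None


def reconcile_timing(network: Optional[CardiacEvents],
                     ecg: Optional[CardiacEvents],
                     cutoff_frames: float = DEFAULT_CUTOFF_FRAMES) -> CardiacEvents:
    """Keep the network events unless they stray from the ECG regression.

    The deviation is the maximum of |ΔED| and |ΔES| in frames; *more than*
    ``cutoff_frames`` (strictly) switches to the regression result, as does
    an absent network output.  Both absent raises
    :class:`TimingUnavailableError`.
    """
    if network is None and ecg is None:
        raise TimingUnavailableError("no timing source available")
    if network is None:
        return ecg
    if ecg is None:
        return network
    deviation = float(max(abs(network.ed_frame - ecg.ed_frame),
                          abs(network.es_frame - ecg.es_frame)))
    if deviation > cutoff_frames:
        return CardiacEvents(ed_frame=ecg.ed_frame, es_frame=ecg.es_frame,
                             source="ecg_regression", deviation_frames=deviation)
    return CardiacEvents(ed_frame=network.ed_frame, es_frame=network.es_frame,
                         source="network", deviation_frames=deviation)


def resolve_events(recording: Recording, patient: PatientInfo,
                   backend: Optional[EventDetectionBackend],
                   cutoff_frames: float = DEFAULT_CUTOFF_FRAMES) -> List[CardiacEvents]:
    """Full per-recording timing: detect, ECG fallback, reconcile per cycle.

    Network cycles are matched to ECG cycles by ED-anchor proximity of
    their ordering (cycle j with cycle j).  Raises
    :class:`TimingUnavailableError` when neither source yields any cycle.
    """
    network = detect_events(recording, backend)
    try:
        ecg = ecg_events_all_cycles(recording, patient)
    except TimingUnavailableError:
        ecg = None

    if network is None and ecg is None:
        raise TimingUnavailableError(
            f"recording {recording.recording_id}: no timing source")
    if network is None:
        return ecg
    if ecg is None:
        return network

    resolved = []
    for j in range(min(len(network), len(ecg))):
        resolved.append(reconcile_timing(network[j], ecg[j], cutoff_frames))
    # network cycles beyond the ECG annotation are kept as-is
    resolved.extend(network[len(ecg):])
    return resolved


# ---------------------------------------------------------------------------
# Shipped backends (for synthetic data and tests)

class OracleTimingBackend:
    """Reads the true event frames from the recording's annotations."""

    def detect(self, recording: Recording) -> Optional[List[Tuple[int, int]]]:
        ann = recording.annotations or {}
        eds, ess = ann.get("ed_frames"), ann.get("es_frames")
        if not eds or not ess:
            return None
        return list(zip(eds, ess))


class DisabledTimingBackend:
    """Always fails, exercising the ECG-regression fallback path."""

    def detect(self, recording: Recording) -> None:
        return None


class BiasedTimingBackend:
    """Oracle shifted by a fixed frame offset, for reconciliation tests."""

    def __init__(self, offset_frames: int):
        self.offset = offset_frames
        self._oracle = OracleTimingBackend()

    def detect(self, recording: Recording) -> Optional[List[Tuple[int, int]]]:
        pairs = self._oracle.detect(recording)
        if pairs is None:
            return None
        shifted = [(ed + self.offset, es + self.offset) for ed, es in pairs]
        if any(not (0 <= ed < es < recording.n_frames) for ed, es in shifted):
            return None
        return shifted
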