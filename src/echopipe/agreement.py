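"""Bland–Altman agreement, subgroup stratification and feasibility funnel.

Phase 3 of the pipeline: paired agreement between automated and reference
measurements (bias = mean difference, limits of agreement = bias ±
1.96·SD of the differences, sample SD with n−1 denominator), stratified
by possibly overlapping subgroup labels (image-quality class, disease
flags, dataset), plus the ordered stage-by-stage exclusion accounting
("funnel") whose final percentage is the feasibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .curation import ExclusionReason

LOA_MULTIPLIER = 1.96

#: ordered pipeline stages; an exam is excluded at exactly one of them
FUNNEL_STAGES = (
    "bmode_present",       # tee_only / no_bmode fail here
    "views_present",       # missing_A4C / missing_A2C
    "confidence_gate",     # low_view_confidence
    "timing",              # timing_unavailable
    "segmentation_valid",  # invalid_segmentation
    "dice_qc",             # low_dice
)

_REASON_TO_STAGE = {
    ExclusionReason.TEE_ONLY: "bmode_present",
    ExclusionReason.NO_BMODE: "bmode_present",
    ExclusionReason.MISSING_A4C: "views_present",
    ExclusionReason.MISSING_A2C: "views_present",
    ExclusionReason.LOW_VIEW_CONFIDENCE: "confidence_gate",
    ExclusionReason.TIMING_UNAVAILABLE: "timing",
    ExclusionReason.INVALID_SEGMENTATION: "segmentation_valid",
    ExclusionReason.LOW_DICE: "dice_qc",
    ExclusionReason.OTHER: "bmode_present",
}


@dataclass
class AgreementStats:
    n: int
    bias: float
    sd: Optional[float]
    loa_low: Optional[float]
    loa_high: Optional[float]

    def as_dict(self) -> dict:
        return {"n": self.n, "bias": self.bias, "sd": self.sd,
                "loa_low": self.loa_low, "loa_high": self.loa_high}


def bland_altman(auto: Sequence[float], ref: Sequence[float],
                 loa_multiplier: float = LOA_MULTIPLIER) -> AgreementStats:
    """Bland–Altman statistics of paired automated vs reference values."""
    a = np.asarray(auto, dtype=float)
    r = np.asarray(ref, dtype=float)
    if a.shape != r.shape or a.ndim != 1:
        raise ValueError(f"auto and ref must be matched 1-D vectors, "
                         f"got {a.shape} and {r.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(n=int(a.size), bias=bias, sd=sd,
                          loa_low=bias - loa_multiplier * sd,
                          loa_high=bias + loa_multiplier * sd)


def stratified_agreement(auto: Sequence[float], ref: Sequence[float],
                         labels: Mapping[str, Sequence],
                         loa_multiplier: float = LOA_MULTIPLIER,
                         ) -> Dict[Tuple[str, str], AgreementStats]:
    """Per-subgroup Bland–Altman statistics.

    ``labels`` maps a key name to one per-pair label vector.  Boolean
    vectors yield a "with"/"without" pair of groups (disease flags may
    overlap across keys, so subgroup n's can sum above the total);
    categorical vectors yield one group per distinct value.  Groups with
    fewer than 2 pairs are reported with their n and no SD.
    """
    a = np.asarray(auto, dtype=float)
    r = np.asarray(ref, dtype=float)
    out: Dict[Tuple[str, str], AgreementStats] = {}
    for key, vec in labels.items():
        vec = np.asarray(vec)
        if vec.shape[0] != a.shape[0]:
            raise ValueError(f"label vector {key!r} length mismatch")
        if vec.dtype == bool:
            groups = {"with": vec, "without": ~vec}
        else:
            groups = {str(v): vec == v for v in sorted(np.unique(vec), key=str)}
        for name, sel in groups.items():
            n = int(sel.sum())
            if n >= 2:
                out[(key, name)] = bland_altman(a[sel], r[sel], loa_multiplier)
            elif n >= 1:
                out[(key, name)] = AgreementStats(
                    n=n, bias=float((a[sel] - r[sel]).mean()),
                    sd=None, loa_low=None, loa_high=None)
            else:
                out[(key, name)] = AgreementStats(n=0, bias=float("nan"),
                                                  sd=None, loa_low=None,
                                                  loa_high=None)
    return out


@dataclass
class FunnelReport:
    """Ordered exclusion accounting; ``feasibility_pct`` is the survivors'
    share of the input."""

    n_input: int
    stages: List[dict]  # {stage, entered, excluded, surviving, reasons}
    n_measured: int
    feasibility_pct: float

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "stages": self.stages,
                "n_measured": self.n_measured,
                "feasibility_pct": self.feasibility_pct}


def feasibility_funnel(terminal_reasons: Sequence[ExclusionReason]) -> FunnelReport:
    """Build the stage-by-stage funnel from per-exam terminal outcomes.

    ``terminal_reasons`` holds one entry per input exam:
    ``ExclusionReason.NONE`` for a measured exam, otherwise the single
    primary reason it was excluded.  Counts conserve at every stage:
    survivors + newly excluded = previous survivors.
    """
    reasons = [ExclusionReason(r) for r in terminal_reasons]
    n_input = len(reasons)
    surviving = n_input
    stages: List[dict] = []
    for stage in FUNNEL_STAGES:
        stage_reasons: Dict[str, int] = {}
        for r in reasons:
            if r is not ExclusionReason.NONE and _REASON_TO_STAGE.get(r) == stage:
                stage_reasons[r.value] = stage_reasons.get(r.value, 0) + 1
        excluded = sum(stage_reasons.values())
        stages.append({
            "stage": stage,
            "entered": surviving,
            "excluded": excluded,
            "surviving": surviving - excluded,
            "reasons": stage_reasons,
        })
        surviving -= excluded
    n_measured = surviving
    if n_measured != sum(1 for r in reasons if r is ExclusionReason.NONE):
        raise ValueError("exam with unmapped terminal status")
    return FunnelReport(
        n_input=n_input,
        stages=stages,
        n_measured=n_measured,
        feasibility_pct=(100.0 * n_measured / n_input) if n_input else 0.0,
    )


def distribution_summary(values: Sequence[float], bins: int = 20,
                         range_: Optional[Tuple[float, float]] = None) -> dict:
    """Histogram plus a Gaussian-KDE smooth of one measurement distribution.

    Degenerate (constant) samples fall back to a single occupied bin with
    no density estimate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    counts, edges = np.histogram(v, bins=bins, range=range_)
    out = {"counts": counts.tolist(), "bin_edges": edges.tolist(),
           "n": int(v.size), "mean": float(v.mean())}
    if v.size >= 2 and np.ptp(v) > 0:
        from scipy import stats

        kde = stats.gaussian_kde(v)
        grid = np.linspace(edges[0], edges[-1], 200)
        out["density_grid"] = grid.tolist()
        out["density"] = kde(grid).tolist()
    return out
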