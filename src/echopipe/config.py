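"""Pipeline configuration: the QC thresholds and numeric conventions."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    confidence_threshold: float = 0.85
    dice_threshold: float = 0.8
    timing_cutoff_frames: float = 5.0
    n_discs: int = 20
    bsa_formula: str = "mosteller"
    seed: int = 0
    modality_backend: str = "oracle"
    view_backend: str = "oracle"
    timing_backend: str = "oracle"

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if not (0.0 <= self.dice_threshold <= 1.0):
            raise ValueError("dice_threshold must lie in [0, 1]")
        if self.timing_cutoff_frames < 0:
            raise ValueError("timing_cutoff_frames must be non-negative")
        if self.n_discs < 2:
            raise ValueError("n_discs must be >= 2")
        if self.bsa_formula not in ("mosteller", "dubois"):
            raise ValueError(f"unknown bsa_formula {self.bsa_formula!r}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return asdict(self)
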