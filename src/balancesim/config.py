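"""Run configuration: one YAML document driving simulation, optimization
and analysis, with a recorded global seed for reproducibility."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .objective import DOFLimits, ObjectiveWeights
from .perturbation import Protocol


@dataclass
class RunConfig:
    protocol: Protocol = field(default_factory=Protocol)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    limits: DOFLimits = field(default_factory=DOFLimits)
    dt: float = 1e-3
    seed: int = 0
    restarts: int = 8
    max_generations: int = 150
    ftarget: float | None = 5.0
    total_mass: float = 74.5
    height: float = 1.8
    out_dir: str = "results"
    full_scale: bool = False   # study-scale budget: 60 restarts, no ftarget

    def resolved_restarts(self) -> int:
        return 60 if self.full_scale else self.restarts

    def resolved_ftarget(self) -> float | None:
        return None if self.full_scale else self.ftarget

    def digest(self) -> str:
        """Short content hash logged with every artifact."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = dict(raw)
        if "protocol" in kw:
            p = kw["protocol"]
            kw["protocol"] = Protocol(
                magnitudes_mm=tuple(p.get("magnitudes_mm",
                                          Protocol().magnitudes_mm)),
                delays_ms=tuple(p.get("delays_ms", Protocol().delays_ms)),
                frequency=p.get("frequency", 1.0),
                duration=p.get("duration", 10.0))
        if "weights" in kw:
            kw["weights"] = ObjectiveWeights(**kw["weights"])
        if "limits" in kw:
            kw["limits"] = DOFLimits(**kw["limits"])
        return cls(**kw)
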