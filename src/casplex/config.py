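"""Run configuration: defaults, YAML loading, validation and hashing.

Every CLI artifact embeds the configuration hash so a run can be
reproduced exactly from the file header alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .genotyping import ThresholdSet
from .lfa import LFAThresholds
from .simulate import NOISE_PRESETS, SignalModelParams


@dataclass
class ClassifierConfig:
    n_estimators: int = 40
    n_intervals: int | None = None
    train_frac: float = 0.7
    n_splits: int = 100

    def validate(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0,1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass
class ScoringConfig:
    background_mode: str = "auto"     # auto | ntc | first-point
    slope_window: tuple[float, float] = (5.0, 60.0)

    def validate(self) -> None:
        if self.background_mode not in ("auto", "ntc", "first-point"):
            raise ValueError(f"unknown background mode {self.background_mode!r}")
        lo, hi = self.slope_window
        if not lo < hi:
            raise ValueError("slope window must satisfy lo < hi")


@dataclass
class SimulateConfig:
    n_per_genotype: int = 20
    replicate_count: int = 6
    n_batches: int = 1
    noise_preset: str = "moderate"

    def validate(self) -> None:
        if self.n_per_genotype < 1 or self.replicate_count < 1 or self.n_batches < 1:
            raise ValueError("simulation sizes must be >= 1")
        if self.noise_preset not in NOISE_PRESETS:
            raise ValueError(f"unknown noise preset {self.noise_preset!r}")

    def signal_params(self) -> SignalModelParams:
        return SignalModelParams().with_noise_preset(self.noise_preset)


@dataclass
class RunConfig:
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    lfa_thresholds: LFAThresholds = field(default_factory=LFAThresholds)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.scoring.validate()
        self.classifier.validate()
        self.simulate.validate()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "RunConfig":
        import yaml

        cfg = cls()
        if path is None:
            return cfg.validate()
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {"thresholds", "lfa_thresholds", "scoring",
                               "classifier", "simulate", "seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        if "thresholds" in data:
            cfg.thresholds = ThresholdSet(**data["thresholds"])
        if "lfa_thresholds" in data:
            cfg.lfa_thresholds = LFAThresholds(**data["lfa_thresholds"])
        if "scoring" in data:
            cfg.scoring = ScoringConfig(**{**data["scoring"],
                                           "slope_window": tuple(data["scoring"].get(
                                               "slope_window", (5.0, 60.0)))})
        if "classifier" in data:
            cfg.classifier = ClassifierConfig(**data["classifier"])
        if "simulate" in data:
            cfg.simulate = SimulateConfig(**data["simulate"])
        cfg.seed = int(data.get("seed", 0))
        return cfg.validate()

    def hash(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        from . import __version__
        return f"casplex v{__version__} config={self.hash()} seed={self.seed}"
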