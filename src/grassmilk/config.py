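"""Pipeline configuration: nested blocks, validation and stable hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .schema import ARCHETYPE_DEFAULTS
from .simdata import DEFAULT_ARCHETYPE_MIX

__all__ = ["PipelineConfig", "SimulationBlock", "LabelingBlock", "ModelBlock", "TypologyBlock"]


@dataclass
class SimulationBlock:
    n_farms: int = 60
    n_years: int = 3
    seed: int = 7
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX)
    )
    transition_width: float = 1.5
    fa_noise_rho: float = 0.3

    def validate(self) -> None:
        if self.n_farms < 2:
            raise ConfigurationError("simulation.n_farms must be >= 2")
        if self.n_years < 1:
            raise ConfigurationError("simulation.n_years must be >= 1")
        unknown = set(self.archetype_mix) - set(ARCHETYPE_DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown archetypes: {sorted(unknown)}")
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("simulation.archetype_mix must sum to 1")
        if not 0.0 <= self.fa_noise_rho < 1.0:
            raise ConfigurationError("simulation.fa_noise_rho must lie in [0, 1)")


@dataclass
class LabelingBlock:
    schemes: list[int] = field(default_factory=lambda: [1, 2, 3])
    calibration_fraction: float = 0.30

    def validate(self) -> None:
        if not self.schemes or any(s not in (1, 2, 3) for s in self.schemes):
            raise ConfigurationError("labeling.schemes must be a subset of {1,2,3}")
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ConfigurationError("labeling.calibration_fraction must lie in (0,1)")


@dataclass
class ModelBlock:
    max_components: int = 30
    folds: int = 10
    vip_threshold: float = 50.0

    def validate(self) -> None:
        if not 1 <= self.max_components <= 30:
            raise ConfigurationError("model.max_components must lie in 1..30")
        if self.folds < 2:
            raise ConfigurationError("model.folds must be >= 2")
        if not 0.0 <= self.vip_threshold <= 100.0:
            raise ConfigurationError("model.vip_threshold must lie in [0, 100]")


@dataclass
class TypologyBlock:
    scheme: int = 1
    k: int = 12
    fat_threshold: float = 1.0
    #: cluster id → −1 (intensive) / +1 (extensive); None = derive from the
    #: clusters' overall probability level after clustering
    group_map: dict[int, int] | None = None

    def validate(self) -> None:
        if self.scheme not in (1, 2, 3):
            raise ConfigurationError("typology.scheme must be 1, 2 or 3")
        if self.k < 1:
            raise ConfigurationError("typology.k must be >= 1")
        if self.group_map is not None and any(
            v not in (-1, 1) for v in self.group_map.values()
        ):
            raise ConfigurationError("typology.group_map values must be -1 or +1")


@dataclass
class PipelineConfig:
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    labeling: LabelingBlock = field(default_factory=LabelingBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    typology: TypologyBlock = field(default_factory=TypologyBlock)
    output_dir: str = "results/pipeline"

    def validate(self) -> None:
        self.simulation.validate()
        self.labeling.validate()
        self.model.validate()
        self.typology.validate()
        if self.typology.scheme not in self.labeling.schemes:
            raise ConfigurationError(
                "typology.scheme must be among the trained labeling.schemes"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        cfg = cls(
            simulation=SimulationBlock(**data.pop("simulation", {})),
            labeling=LabelingBlock(**data.pop("labeling", {})),
            model=ModelBlock(**data.pop("model", {})),
            typology=TypologyBlock(**data.pop("typology", {})),
            output_dir=data.pop("output_dir", "results/pipeline"),
        )
        if data:
            raise ConfigurationError(f"unknown config keys: {sorted(data)}")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the canonicalised configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]
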