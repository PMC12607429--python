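"""YAML pipeline configuration.

A :class:`PipelineConfig` fully determines a run: the simulated study (or
paths to real exports), windowing geometry, feature-selection thresholds,
the model, and the evaluation protocol.  Unknown keys are rejected rather
than ignored so typos cannot silently change an experiment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .evaluation import SelectionParams, SplitProtocol
from .io import ValidationError
from .models import ClassifierSpec
from .segmentation import WindowingParams
from .simulate import DurationDistribution, SimulationConfig


class ConfigError(ValidationError):
    """A configuration file is malformed or carries unknown keys."""


def _from_mapping(cls, mapping: dict, context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    mapping = dict(mapping or {})
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) {unknown} in section {context!r}")
    return cls(**mapping)


@dataclass
class ModelConfig:
    kind: str = "random_forest"  # family name or 'heuristic'
    hyperparameters: dict = field(default_factory=dict)
    standardize_features: bool | None = None
    seed: int = 0

    def resolve(self):
        if self.kind == "heuristic":
            return "heuristic"
        return ClassifierSpec(
            family=self.kind,
            hyperparameters=dict(self.hyperparameters),
            standardize_features=self.standardize_features,
            seed=self.seed,
        )


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    windowing: WindowingParams = field(default_factory=WindowingParams)
    features: SelectionParams = field(default_factory=SelectionParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    protocol: SplitProtocol = field(default_factory=SplitProtocol)
    event_length: float = 7.8
    write_data: bool = False  # also write the simulated CSVs next to the report
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping or {})
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {unknown}")
        sim_map = dict(mapping.pop("simulation", {}) or {})
        if "duration_distribution" in sim_map:
            sim_map["duration_distribution"] = _from_mapping(
                DurationDistribution,
                sim_map["duration_distribution"],
                "simulation.duration_distribution",
            )
        if "events_per_subject" in sim_map:
            sim_map["events_per_subject"] = tuple(sim_map["events_per_subject"])
        if sim_map.get("subject_ids") is not None:
            sim_map["subject_ids"] = tuple(sim_map["subject_ids"])
        return cls(
            simulation=_from_mapping(SimulationConfig, sim_map, "simulation"),
            windowing=_from_mapping(WindowingParams, mapping.pop("windowing", {}), "windowing"),
            features=_from_mapping(SelectionParams, mapping.pop("features", {}), "features"),
            model=_from_mapping(ModelConfig, mapping.pop("model", {}), "model"),
            protocol=_from_mapping(SplitProtocol, mapping.pop("protocol", {}), "protocol"),
            **mapping,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        return cls.from_mapping(mapping)

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the fully resolved configuration."""
        canon = json.dumps(self.to_mapping(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
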