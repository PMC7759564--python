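"""Pipeline configuration: one dataclass, YAML round-trip, flag overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Every tunable of the detection/network stages, with defaults."""

    anchor_length: int = 20
    index_k: int = 12
    max_mismatches_linear: int = 2
    max_mismatches_anchor: int = 0
    max_mismatches_extend: int = 2
    min_reads: int = 2
    max_span: int = 100_000
    mfe_threshold: float = -20.0
    score_threshold: float = 90.0
    circ_max_len: int = 2000
    unique_anchors: bool = True
    dedupe_fragments: bool = False
    seed: int = 0
    #: free-form parameters for the synthetic-data subcommand
    simulate: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchor_length < self.index_k:
            raise ConfigurationError(
                f"anchor_length ({self.anchor_length}) must be >= index k "
                f"({self.index_k})"
            )
        if self.index_k < 8:
            raise ConfigurationError("index_k must be >= 8")
        if self.min_reads < 1:
            raise ConfigurationError("min_reads must be >= 1")
        if not 0 <= self.max_mismatches_anchor <= 2:
            raise ConfigurationError("max_mismatches_anchor must be in 0..2")

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    def replace(self, **overrides: Any) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig.from_dict(data)
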