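"""Pipeline configuration: one structured object, YAML-serializable.

All stage randomness flows from a single root seed, expanded per stage
with fixed offsets so stages stay independent yet reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

_STAGE_OFFSETS = {
    "synth": 1,
    "filter": 2,
    "stain": 3,
    "train": 4,
    "predict": 5,
    "evaluate": 6,
    "gradcam": 7,
}


@dataclass
class PipelineConfig:
    # dataset synthesis
    n_slides_per_leaf: int = 8
    slide_size: int = 600
    background_fraction: float = 0.25
    train_fraction: float = 0.75
    # patching
    patch_size: int = 200
    stride: int | None = None
    # patch filter
    filter_input_size: int = 64
    filter_bottleneck: int = 64
    filter_epochs: int = 5
    kmeans_restarts: int = 10
    # training (working scale: patches downscaled to model_input_size)
    model_input_size: int = 100
    parent_epochs: int = 40
    child_epochs: int = 80
    batch_size: int = 16
    learning_rate: float = 0.003
    validation_fraction: float = 0.1
    augment: bool = True
    # global
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        return (self.seed * 1000003 + _STAGE_OFFSETS[stage]) % (2**31)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
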