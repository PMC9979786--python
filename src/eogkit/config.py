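"""One-file run configuration driving the whole pipeline.

A YAML document with nested sections (``simulator``, ``filter``,
``thresholds``, ``knn``, ``cnn``, ``stream``) plus a top-level ``seed``.
Every field is optional and falls back to the documented dataclass
default; unknown keys are rejected by name so typos fail loudly.
CLI flags override file values (flag > file > default).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cnn import CNNConfig
from .knn import KNNConfig
from .preprocess import FilterSpec
from .simulate import SimulatorConfig
from .stream import StreamConfig
from .types import ValidationError

_SECTIONS = {
    "simulator": SimulatorConfig,
    "filter": FilterSpec,
    "knn": KNNConfig,
    "cnn": CNNConfig,
    "stream": StreamConfig,
}

# thresholds section: optional explicit thresholds; absent -> calibrate.
_THRESHOLD_KEYS = {"horiz_thresh", "vert_thresh", "blink_thresh", "blink_max_width"}


def _build(cls, section: str, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValidationError(f"unknown key(s) in section {section!r}: {unknown}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for every pipeline stage."""

    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    thresholds: dict = field(default_factory=dict)
    knn: KNNConfig = field(default_factory=KNNConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    stream: StreamConfig = field(default_factory=StreamConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = sorted(set(self.thresholds) - _THRESHOLD_KEYS)
        if unknown:
            raise ValidationError(f"unknown key(s) in section 'thresholds': {unknown}")

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for name, cls in _SECTIONS.items():
            section = data.pop(name, {})
            if not isinstance(section, dict):
                raise ValidationError(f"section {name!r} must be a mapping")
            kwargs[name] = _build(cls, name, section)
        kwargs["thresholds"] = data.pop("thresholds", {}) or {}
        kwargs["seed"] = int(data.pop("seed", 0))
        if data:
            raise ValidationError(f"unknown top-level key(s): {sorted(data)}")
        return RunConfig(**kwargs)

    def to_dict(self) -> dict:
        out: dict = {
            name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS
        }
        out["thresholds"] = dict(self.thresholds)
        out["seed"] = self.seed
        # tuples do not survive a YAML round-trip; normalize to lists
        for mod in ("module_a", "module_b"):
            out["cnn"][mod] = list(out["cnn"][mod])
        return out

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cnn = data.get("cnn") or {}
        for mod in ("module_a", "module_b"):
            if mod in cnn:
                cnn[mod] = tuple(cnn[mod])
        return RunConfig.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def with_seed(self, seed: int | None) -> "RunConfig":
        if seed is None:
            return self
        sim = dataclasses.replace(self.simulator, seed=seed)
        cnn = dataclasses.replace(self.cnn, seed=seed)
        return dataclasses.replace(self, simulator=sim, cnn=cnn, seed=seed)
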