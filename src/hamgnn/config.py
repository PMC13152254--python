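"""Run configuration: a flat-sectioned YAML file mirroring the dataclasses.

The file has top-level keys ``seed``, ``log_level`` and the sections
``model``, ``split``, ``pipeline``, ``synthetic``, ``perturb``; each
section's keys map one-to-one onto the corresponding dataclass fields.
Unknown keys anywhere are rejected, and a loaded config serializes back to
an equivalent document (lossless round-trip).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .perturb import PerturbationSpec
from .pipeline import PipelineConfig
from .synthetic import SyntheticSpec
from .train import SplitSpec

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTIONS = {
    "model": ModelConfig,
    "split": SplitSpec,
    "synthetic": SyntheticSpec,
    "perturb": PerturbationSpec,
}
_PIPELINE_FIELDS = [f.name for f in dataclasses.fields(PipelineConfig)
                    if f.name not in ("model", "split")]


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    perturb: PerturbationSpec = field(default_factory=PerturbationSpec)
    pipeline: dict = field(default_factory=dict)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(model=self.model, split=self.split, **self.pipeline)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "log_level": self.log_level}
        for name, cls in _SECTIONS.items():
            d = dataclasses.asdict(getattr(self, name))
            for k, v in d.items():
                if isinstance(v, tuple):
                    d[k] = list(v)
            out[name] = d
        out["pipeline"] = dict(self.pipeline)
        return out


def _build_section(name: str, cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    tuple_fields = {
        f.name for f in dataclasses.fields(cls)
        if "tuple" in str(f.type)
    }
    kwargs = {
        k: tuple(v) if k in tuple_fields and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_top = {"seed", "log_level", "pipeline"} | set(_SECTIONS)
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "log_level" in raw:
        kwargs["log_level"] = str(raw["log_level"])
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(name, cls, raw[name] or {})
    if "pipeline" in raw:
        pl = raw["pipeline"] or {}
        unknown = set(pl) - set(_PIPELINE_FIELDS)
        if unknown:
            raise ValueError(f"unknown keys in section 'pipeline': {sorted(unknown)}")
        kwargs["pipeline"] = pl
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
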