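"""Structured run configuration with YAML round-trip and override precedence.

A :class:`RunConfig` bundles everything a run needs: input paths, graph
settings, the GCN architecture, the cross-validation scheme, and the
synthetic-cohort spec.  Defaults reproduce the published configuration
(sigma = 1.6, 3 layers, 128 filters, weighted loss, 5-fold x 50-repeat CV
with unlabeled subjects included).  Precedence is CLI flag > config file >
defaults, and the resolved configuration is persisted alongside every
output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import CVScheme
from .gcn import GCNConfig
from .graph import DEFAULT_SIGMA
from .synthetic import SyntheticSpec


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    manifest: str | None = None
    connectome_dir: str | None = None
    output_dir: str = "results"
    sigma: float = DEFAULT_SIGMA
    sigma_grid: list[float] | None = None
    kernel: str = "gaussian"
    standardize: bool = False
    gcn: GCNConfig = field(default_factory=GCNConfig)
    cv: CVScheme = field(default_factory=CVScheme)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, sub_cls in (("gcn", GCNConfig), ("cv", CVScheme), ("synthetic", SyntheticSpec)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub_cls(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (CLI > file > defaults).

        Dotted keys reach into sub-configs, e.g. ``gcn.seed`` or
        ``cv.n_repeats``.
        """
        data = self.to_dict()
        for key, value in overrides.items():
            if value is None:
                continue
            if "." in key:
                head, tail = key.split(".", 1)
                if head not in data or not isinstance(data[head], dict):
                    raise ConfigError(f"unknown config group {head!r}")
                if tail not in data[head]:
                    raise ConfigError(f"unknown config key {key!r}")
                data[head][tail] = value
            else:
                if key not in data:
                    raise ConfigError(f"unknown config key {key!r}")
                data[key] = value
        return RunConfig.from_dict(data)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    base = RunConfig.from_yaml(path) if path else RunConfig()
    return base.merged(**overrides)
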