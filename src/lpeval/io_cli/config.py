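"""Run configuration: nested stage parameters with strict key checking.

Configs round-trip losslessly through YAML; unknown keys are rejected with
the offending section and key named.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from ..errors import ConfigurationError
from ..simdata import SimConfig


@dataclass
class DownsampleConfig:
    enabled: bool = False
    fraction: float | None = None
    target_mean_depth: float | None = None


@dataclass
class ImputeStageConfig:
    switch_rate: float = 1e-6
    mismatch_rate: float = 1e-3
    max_panel: int = 100
    gpmax_threshold: float = 0.9
    base_error: float = 0.01
    enabled: bool = True        # disabled = substitute truth genotypes


@dataclass
class AgreementConfig:
    min_compared: int = 1
    window: int = 1_000_000
    pass_rate_threshold: float = 0.95
    maf_bin: float = 0.01


@dataclass
class GblupConfig:
    relationship: str = "Gstar"   # A | G | Gstar
    reml_method: str = "ai"


@dataclass
class EffectsConfig:
    n_perm: int = 100
    n_keep: int = 20
    percentile: float = 99.0
    random_subset_size: int = 50


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    impute: ImputeStageConfig = field(default_factory=ImputeStageConfig)
    agreement: AgreementConfig = field(default_factory=AgreementConfig)
    gblup: GblupConfig = field(default_factory=GblupConfig)
    effects: EffectsConfig = field(default_factory=EffectsConfig)

    def __post_init__(self):
        # keep the master seed authoritative for the simulation stage
        self.sim.seed = self.seed

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, section="<root>")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["fixed_effect_levels"] = list(d["sim"]["fixed_effect_levels"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _build(cls, data: dict, section: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(section, f"expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(section, f"unknown keys: {sorted(unknown)}")
    kwargs = {}
    nested = {
        "sim": SimConfig,
        "downsample": DownsampleConfig,
        "impute": ImputeStageConfig,
        "agreement": AgreementConfig,
        "gblup": GblupConfig,
        "effects": EffectsConfig,
    }
    for key, value in data.items():
        if key in nested and cls is RunConfig:
            kwargs[key] = _build(nested[key], value, section=key)
        elif key == "fixed_effect_levels":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)
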