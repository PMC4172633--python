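"""Pipeline configuration: one YAML file drives every stage.

Exactly one input source per run: either real war/capability files (with
optional dialect overrides) or a simulator configuration.  CLI flags
override config keys one-for-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .ingest import CapabilityDialect, WarDialect
from .prep import MEASURES
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    war_file: str | None = None
    capabilities_file: str | None = None
    simulator: SimulationConfig | None = None
    war_dialect: WarDialect = field(default_factory=WarDialect)
    cap_dialect: CapabilityDialect = field(default_factory=CapabilityDialect)
    measures: tuple = MEASURES
    alpha: float = 0.05
    trend_alpha: float = 0.10
    tie_break: str = "war_id"
    rpd_kind: str = "bounded"
    standardize: bool = True
    df_method: str = "satterthwaite"
    missing_policy: str = "per-measure"
    min_dyads: int = 10
    seed: int = 0
    output_dir: str = "contestkit_run"

    def __post_init__(self):
        real = self.war_file is not None or self.capabilities_file is not None
        if real and self.simulator is not None:
            raise ValueError("configure either real input files or a "
                             "simulator, not both")
        if real and (self.war_file is None or
                     self.capabilities_file is None):
            raise ValueError("real input needs both war_file and "
                             "capabilities_file")
        if not (0 < self.alpha < self.trend_alpha < 1):
            raise ValueError("need 0 < alpha < trend_alpha < 1")


def _build(cls, mapping):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**mapping)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML pipeline config; ``overrides`` win over file keys."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    for key, cls in (("simulator", SimulationConfig),
                     ("war_dialect", WarDialect),
                     ("cap_dialect", CapabilityDialect)):
        if isinstance(raw.get(key), dict):
            raw[key] = _build(cls, raw[key])
    if "measures" in raw:
        raw["measures"] = tuple(raw["measures"])
    return _build(PipelineConfig, raw)
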