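"""Analysis configuration: layer boundaries, thresholds, statistical
settings. Loadable from YAML with dotted keys mirroring the dataclass
structure (e.g. ``layers.hypolimnion_top``)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .data_model import ValidationError


@dataclass
class LayersConfig:
    epilimnion_top: float = 0.0
    epilimnion_bottom: float = 6.0
    hypolimnion_top: float = 14.0
    hypolimnion_bottom: float = 24.0


@dataclass
class StratificationConfig:
    upper_temp_c: float = 6.0
    lower_temp_c: float = 4.0
    boundary_m: float = 14.0


@dataclass
class AnoxiaConfig:
    threshold_mg_l: float = 1.0
    period: str = "annual"  # "annual" | "stratified"

    def __post_init__(self) -> None:
        if self.period not in ("annual", "stratified"):
            raise ValidationError(f"unknown anoxia period {self.period!r}")


@dataclass
class TEAConfig:
    w_so4: float = 0.197
    w_no3: float = 0.84


@dataclass
class RatesConfig:
    oxygen_max_points: int = 4


@dataclass
class HWConfig:
    model_intercept: float = 0.471
    model_slope: float = 0.331
    export_units: str = "mg_per_m2"


@dataclass
class StatsConfig:
    b: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    davies_k: int = 10


@dataclass
class AnalysisConfig:
    layers: LayersConfig = field(default_factory=LayersConfig)
    stratification: StratificationConfig = field(default_factory=StratificationConfig)
    anoxia: AnoxiaConfig = field(default_factory=AnoxiaConfig)
    tea: TEAConfig = field(default_factory=TEAConfig)
    rates: RatesConfig = field(default_factory=RatesConfig)
    hw: HWConfig = field(default_factory=HWConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        sections = {
            "layers": LayersConfig,
            "stratification": StratificationConfig,
            "anoxia": AnoxiaConfig,
            "tea": TEAConfig,
            "rates": RatesConfig,
            "hw": HWConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            if name in data and data[name] is not None:
                kwargs[name] = klass(**data[name])
        unknown = set(data) - set(sections)
        if unknown:
            raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
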