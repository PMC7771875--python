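"""Run configuration: a serializable description of one pipeline run."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ConfigError
from .protocol import AsymParams, SaturationProtocol


@dataclass(frozen=True)
class RunConfig:
    """Configuration of ``run_pipeline``: cohort source, classification
    rules, protocol/asymmetry parameters, seed, and output directory.

    ``cohort_source`` is ``"fixture"`` (the packaged reference cohort),
    ``"simulate"`` (seeded cohort simulator at its defaults), or ``"csv"``
    (read ``cohort_path``).  Unknown keys in a config file are rejected.
    """

    seed: int = 0
    cohort_source: str = "fixture"
    cohort_path: str | None = None
    rules: tuple = ("mean:2.0", "max:2.48")
    prob_cutoff: float = 0.38
    predictors: tuple = ("mean", "max", "range")
    output_dir: str = "aptwq-out"
    log_level: str = "INFO"
    protocol: dict = field(default_factory=dict)
    asym: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cohort_source not in ("fixture", "simulate", "csv"):
            raise ConfigError(f"unknown cohort_source {self.cohort_source!r}")
        if self.cohort_source == "csv" and not self.cohort_path:
            raise ConfigError("cohort_source 'csv' requires cohort_path")
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(self, "predictors", tuple(self.predictors))
        # validate eagerly so bad configs fail at load time
        SaturationProtocol.from_dict(self.protocol)
        AsymParams.from_dict(self.asym)

    def saturation_protocol(self) -> SaturationProtocol:
        return SaturationProtocol.from_dict(self.protocol)

    def asym_params(self) -> AsymParams:
        return AsymParams.from_dict(self.asym)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rules"] = list(self.rules)
        d["predictors"] = list(self.predictors)
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        return cls.from_dict(json.loads(p.read_text()))
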