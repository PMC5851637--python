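"""Run configuration: one serialisable record of every tunable setting.

A :class:`RunConfig` collects the parameter ranges, design size, master
seed, solver settings, feature thresholds and forest hyperparameters of a
pipeline run.  It round-trips through YAML, and the settings it carries are
embedded into every database's provenance, so a run can be reproduced from
its outputs alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .sampling import ParameterSpace

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults mirror the package-wide study conditions."""

    n: int = 2000
    seed: int = 0
    workers: int = 1
    # solver
    duration: float = 20.0
    burn_in: float = 10.0
    sample_rate: float = 512.0
    # feature thresholds
    eps_amp: float = 1e-2
    # forest hyperparameters
    trees: int = 100
    min_leaf: int = 50
    mtry: int | None = None
    ratios: bool = False
    # parameter ranges: list of {name, min, max[, nominal]}; None = default
    ranges: list | None = None
    outputs: dict = field(default_factory=dict)

    def space(self) -> ParameterSpace:
        if self.ranges is None:
            return ParameterSpace()
        dims, nominal = [], {}
        for rec in self.ranges:
            dims.append((str(rec["name"]), float(rec["min"]), float(rec["max"])))
            if "nominal" in rec:
                nominal[str(rec["name"])] = float(rec["nominal"])
        return ParameterSpace(dimensions=tuple(dims), nominal=nominal)

    def sim_config(self) -> dict:
        return {
            "duration": self.duration,
            "burn_in": self.burn_in,
            "sample_rate": self.sample_rate,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        """Copy with non-None keyword overrides (command-line flags win)."""
        data = asdict(self)
        for key, value in kwargs.items():
            if key not in data:
                raise KeyError(key)
            if value is not None:
                data[key] = value
        return RunConfig(**data)
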