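"""Pipeline configuration: one serializable object drives every stage.

Every run writes its resolved configuration (YAML) next to its outputs so
results can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    dys_channel: str | int = "DYS"
    lam_channel: str | int = "LAMA2"
    min_area: int = 100
    laminin_threshold: float | str = "auto"
    ring_width: int = 3
    n_arcs: int = 360
    smooth_window: int = 3
    pool_window: int = 5
    positivity_threshold: float | str = "auto"
    positivity_relative_fraction: float = 0.5
    border_margin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ConfigError("min_area must be >= 1")
        if self.ring_width < 1:
            raise ConfigError("ring_width must be >= 1")
        if self.n_arcs < 4:
            raise ConfigError("n_arcs must be >= 4")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be a positive odd number")
        if not 0.0 <= self.positivity_relative_fraction < 1.0:
            raise ConfigError("positivity_relative_fraction must be in [0, 1)")
        if self.pool_window < 1 or self.pool_window % 2 == 0:
            raise ConfigError("pool_window must be a positive odd number")
        for name in ("laminin_threshold", "positivity_threshold"):
            v = getattr(self, name)
            if v != "auto":
                v = float(v)
                if not 0 <= v <= 65535:
                    raise ConfigError(f"{name}={v} outside [0, 65535]")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
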