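"""Run configuration: ROI, grid, model and detection-limit settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .regression import MODEL_KINDS
from .roi import BT601_WEIGHTS


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the standard protocol
    (200 px search window, weight grid -1..1 in steps of 0.05, three
    candidate regression models, 3-sigma detection limit)."""

    window: int = 200
    stride: int = 10
    window_statistic: str = "mean"
    gray_weights: tuple[float, float, float] = BT601_WEIGHTS
    grid_step: float = 0.05
    grid_lo: float = -1.0
    grid_hi: float = 1.0
    models: tuple[str, ...] = MODEL_KINDS
    tie_round: int = 6
    select_round: int = 3
    lod_k: float = 3.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.window < 3:
            raise ValueError("window must be at least 3 px")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_lo >= self.grid_hi:
            raise ValueError("grid range must satisfy lo < hi")
        for kind in self.models:
            if kind not in MODEL_KINDS:
                raise ValueError(f"unknown model kind {kind!r}")
        if not self.models:
            raise ValueError("at least one model must be configured")
        if self.lod_k <= 0:
            raise ValueError("lod_k must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gray_weights"] = list(self.gray_weights)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gray_weights" in d:
            d["gray_weights"] = tuple(d["gray_weights"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
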