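"""Run configuration loading and validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ..grids import ConfigurationError
from ..synth import SimulationConfig


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str = "lakecover_run"
    seed: int = 0
    method: str = "fused"  # mlc | svm | fused | auto
    kernel: str = "rbf"
    gamma: float | None = None
    C: float = 1.0
    epsilon: float | None = None
    alpha: float = 0.05
    per_class_train: int = 50
    frequency_scheme: str = "water"
    stability_breaks: tuple[float, ...] | None = None
    presence_rule: str = "majority"
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        if self.method not in ("mlc", "svm", "fused", "auto"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.kernel not in ("rbf", "linear"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["signature_table"] = {
            str(k): list(v)
            for k, v in d["simulation"]["signature_table"].items()}
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json"
            else yaml.safe_load(text)) or {}
    sim = data.pop("simulation", {})
    if "signature_table" in sim:
        sim["signature_table"] = {
            int(k): tuple(v) for k, v in sim["signature_table"].items()}
    if "stability_breaks" in data and data["stability_breaks"] is not None:
        data["stability_breaks"] = tuple(data["stability_breaks"])
    try:
        return RunConfig(simulation=SimulationConfig(**sim), **data)
    except TypeError as exc:
        raise ConfigurationError(f"invalid config: {exc}") from exc
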