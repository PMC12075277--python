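"""Pipeline configuration: protocol constants, fit gates, paths, logging."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biphasic import IndentationProtocol, STUDY_PROTOCOL
from .composition import DEFAULT_RHO_RATIO
from .fitting import FitConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    Defaults are the study conditions: the standard indentation protocol,
    r^2 gate 0.70, a/h gate 0.55, thickness correction off, PBS/water
    density ratio 1.005.
    """

    out_dir: Path = Path("results/pipeline")
    seed: int = 0
    n_donors_per_group: int = 6
    protocol: IndentationProtocol = STUDY_PROTOCOL
    fit: FitConfig = field(default_factory=FitConfig)
    rho_ratio: float = DEFAULT_RHO_RATIO
    noise_sd_um: float = 0.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        logging.basicConfig(level=getattr(logging, self.log_level.upper(), logging.INFO))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional JSON/YAML file plus keyword overrides.

    The file may set any top-level PipelineConfig field; ``protocol`` and
    ``fit`` entries are nested mappings.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
    data.update(overrides)
    if isinstance(data.get("protocol"), dict):
        data["protocol"] = IndentationProtocol(**data["protocol"])
    if isinstance(data.get("fit"), dict):
        data["fit"] = FitConfig(**data["fit"])
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
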