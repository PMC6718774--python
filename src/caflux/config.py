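"""Run configuration: every user parameter of the pipeline in one place.

Configs load from TOML or JSON.  Unknown keys are rejected so typos fail
early, and the fully resolved parameter set is echoed into the output
directory by the pipeline, making every run a pure function of
(inputs, resolved config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .network import CorrelationSpec, NetworkParams
from .segmentation import SegmentationParams
from .timeseries import SpikeParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters for a full pipeline run."""

    frames: tuple[str, ...] = ()
    video: str | None = None
    fps: float = 1.0
    um_per_px: float = 1.0
    reference_frame: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spikes: SpikeParams = field(default_factory=SpikeParams)
    correlation: CorrelationSpec = field(default_factory=CorrelationSpec)
    network: NetworkParams = field(default_factory=NetworkParams)
    out_dir: str = "caflux_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frames"] = list(d["frames"])
        return d


_SECTIONS = {
    "segmentation": SegmentationParams,
    "spikes": SpikeParams,
    "correlation": CorrelationSpec,
    "network": NetworkParams,
}
_TOP_KEYS = {"frames", "video", "fps", "um_per_px", "reference_frame", "out_dir"}


def _build(cls, data: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown keys in [{where}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{where}] parameters: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML (.toml) or JSON (.json) run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    elif path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format: {path.suffix}")

    unknown = set(data) - _TOP_KEYS - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    kwargs: dict = {k: data[k] for k in _TOP_KEYS if k in data}
    if "frames" in kwargs:
        kwargs["frames"] = tuple(kwargs["frames"])
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, dict(data[name]), name)
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
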