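"""Run configuration and reproducible RNG stream fan-out."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

#: Named substreams spawned from the single run seed, in fixed order, so each
#: stage (profile sampling, MV noise, duration draws, ...) is independently
#: reproducible.
STREAM_NAMES = (
    "profile",
    "init",
    "at",
    "noise",
    "selection",
    "expand",
    "trace",
    "fixture",
)


def rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Fan a single integer seed out into named, independent RNG streams."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAM_NAMES, children)}


@dataclass(frozen=True)
class RunConfig:
    """Everything one simulation run needs besides the layout itself."""

    seed: int = 0
    total_dur_h: float = 240.0          # 10 days
    norm_mv: float = 200.0
    noise_sigma: float = 1.0            # MV units per sub-step update (0.005*norm_mv)
    substep_min: float = 5.0            # MV update resolution inside an AS
    relax_quantum_min: float = 10.0     # relax is re-evaluated this often
    speed_cm_s: float = 60.0            # walking speed for the location trace
    sample_hz: float = 1.0              # location sampling rate
    layout_path: str | None = None
    profile_path: str | None = None
    sensors_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        positive = {
            "total_dur_h": self.total_dur_h,
            "norm_mv": self.norm_mv,
            "substep_min": self.substep_min,
            "relax_quantum_min": self.relax_quantum_min,
            "speed_cm_s": self.speed_cm_s,
            "sample_hz": self.sample_hz,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ConfigurationError(f"{name} must be positive, got {val}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run-config file; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
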