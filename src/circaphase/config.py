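"""Run configuration and deterministic seeding.

A single master seed lives in :class:`RunConfig`; every stochastic operation
draws its generator from a named substream so that re-running any subset of
the pipeline with the same seed reproduces results exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

SCHEDULE_LABELS = ("FS", "HS", "SWday", "SWnight")


@dataclass
class RunConfig:
    """Pipeline configuration.

    Defaults reproduce the published model configuration: 30-minute bins,
    light lags spanning 0-24 h, temperature lags 0-5 h, 5 hidden neurons and
    100 random training restarts.
    """

    schedule_label: str = "FS"
    bin_minutes: int = 30
    light_lag_hours: float = 24.0
    temp_lag_hours: float = 5.0
    hidden_neurons: int = 5
    restarts: int = 100
    rng_seed: int = 0
    # training controls (substitutes for unstated originals)
    max_epochs: int = 1000
    step_tol: float = 1e-6
    # reference-waveform noise
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.schedule_label not in SCHEDULE_LABELS:
            raise ValueError(f"unknown schedule_label {self.schedule_label!r}")
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child generator of a master seed.

    The substream key is a CRC32 of ``name`` so the mapping is stable across
    processes and Python versions (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, key]))
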