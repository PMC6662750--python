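"""Core domain types shared across the pipeline.

Time is represented internally as minutes of civil local time, measured from
midnight of day 0 of the recording (see :mod:`circaphase.io` for the on-disk
ISO-8601 convention). Clock times are circular on [0, 1440).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440.0

#: closed vocabulary of skin-temperature sites
TEMPERATURE_SITES = ("shoulder", "sternum", "wrist", "thigh", "calf", "ankle", "foot")
#: sites recorded bilaterally (sternum is single, midline)
BILATERAL_SITES = ("shoulder", "wrist", "thigh", "calf", "ankle", "foot")


class SchemaError(ValueError):
    """Input table violates the documented schema."""


class EmptyChannelError(ValueError):
    """A cleaning step removed every sample of a channel."""


def wrap_minutes(delta: float | np.ndarray) -> float | np.ndarray:
    """Wrap a signed minute difference to (-720, +720]."""
    w = -((-np.asarray(delta, dtype=float) + 720.0) % MINUTES_PER_DAY - 720.0)
    return w if isinstance(delta, np.ndarray) else float(w)


def circular_mean_minutes(times: Sequence[float]) -> float:
    """Circular mean of clock times (minutes past midnight)."""
    ang = 2.0 * np.pi * np.asarray(times, dtype=float) / MINUTES_PER_DAY
    m = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float((m * MINUTES_PER_DAY / (2.0 * np.pi)) % MINUTES_PER_DAY)


@dataclass
class SleepInterval:
    onset: float
    offset: float
    in_lab: bool = False

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise SchemaError(f"sleep offset {self.offset} must exceed onset {self.onset}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


@dataclass
class UrineBlock:
    start: float
    end: float
    volume: float  # mL
    concentration: float  # ng/mL

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise SchemaError(f"urine block end {self.end} must exceed start {self.start}")
        if self.volume < 0 or self.concentration < 0:
            raise SchemaError("urine volume and concentration must be >= 0")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / 60.0


@dataclass
class PhaseEstimate:
    """A circadian phase: a clock time with provenance.

    ``clock_time`` is minutes past local midnight on [0, 1440); differences
    between estimates must use circular arithmetic (:func:`wrap_minutes`).
    """

    clock_time: float
    method: str  # measured | network | mid-sleep | normal-range guess | resampling guess
    marker: str = "aMT6s"  # melatonin | aMT6s
    date: Optional[int] = None  # day index, when meaningful
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.clock_time = float(self.clock_time) % MINUTES_PER_DAY

    @property
    def clock_hours(self) -> float:
        return self.clock_time / 60.0


@dataclass
class ChannelSeries:
    """A timestamped 1-D physiological/environmental signal.

    Missing samples are NaN in ``values``; ``missing_mask`` is derived.
    Cadence must be constant within a series.
    """

    timestamps: np.ndarray
    values: np.ndarray
    channel_kind: str  # light | temperature | activity
    site: Optional[str] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.timestamps.size >= 2:
            d = np.diff(self.timestamps)
            if np.any(d <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(d, d[0], atol=1e-6):
                raise ValueError("cadence must be constant within a series")

    @property
    def cadence(self) -> float:
        if self.timestamps.size < 2:
            return np.nan
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def fraction_missing(self) -> float:
        return float(np.mean(self.missing_mask)) if self.values.size else 1.0

    def copy(self) -> "ChannelSeries":
        return ChannelSeries(
            self.timestamps.copy(), self.values.copy(), self.channel_kind, self.site
        )


@dataclass
class BinnedMatrix:
    """30-min binned channel variables on a common aligned span.

    ``frame`` is indexed by bin-center minutes (centers at :15/:45 for
    30-minute bins starting on the hour or half hour).
    """

    frame: pd.DataFrame

    @property
    def bin_centers(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=float)

    @property
    def columns(self) -> list:
        return list(self.frame.columns)

    @property
    def bin_minutes(self) -> float:
        idx = self.bin_centers
        return float(idx[1] - idx[0]) if idx.size >= 2 else np.nan


@dataclass
class Participant:
    """One participant's raw ambulatory recordings, as loaded from disk."""

    id: str
    actigraphy: pd.DataFrame  # timestamp, blue, white_lux, activity, off_wrist
    temperature: pd.DataFrame  # timestamp, value, site, side
    sleep: list = field(default_factory=list)  # list[SleepInterval]
    urine: list = field(default_factory=list)  # list[UrineBlock]
    melatonin: Optional[pd.DataFrame] = None  # timestamp, value (pg/mL)
    inlab: list = field(default_factory=list)  # list[(start, end)] minutes
    temp_removal_log: list = field(default_factory=list)  # list[(start, end)]
    schedule: str = "FS"
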