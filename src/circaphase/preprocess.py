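"""Cleaning, detrending, gap interpolation, binning and alignment.

Channel-specific rules:

* temperature -- device-removal/off-wrist samples excluded, values below
  20 °C removed, then values beyond mean +/- 3 SD of the remainder; detrended
  by a centred 24-h moving average, z-transformed, |z| > 2 removed.
* light -- off-wrist epochs excluded, wake-time values < 1 (sensor covered by
  clothing) excluded, remaining values floored at 0.01 and log10-transformed.
* activity -- off-wrist epochs excluded, gaps interpolated, values < 0
  clamped to 0, z-transformed, |z| > 2 removed.

Gaps are interpolated with forward/backward autoregressive forecasts blended
across the gap; gaps of three hours or more inside the first recording day
instead truncate the series to the end of the gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BILATERAL_SITES,
    BinnedMatrix,
    ChannelSeries,
    EmptyChannelError,
    SchemaError,
    SleepInterval,
)

logger = logging.getLogger("circaphase")

TEMP_FLOOR_C = 20.0
TEMP_OUTLIER_SD = 3.0
DETREND_OUTLIER_SD = 2.0
LIGHT_WAKE_ARTIFACT = 1.0
LIGHT_FLOOR = 0.01
ACTIVITY_OUTLIER_SD = 2.0

MAX_GAP_HOURS = 36.0
FIRST_DAY_GAP_HOURS = 3.0
SHORT_GAP_HOURS = 1.0
MIN_SPAN_DAYS = 3.0
MAX_MISSING_FRACTION = 0.5


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class ExclusionError(ValueError):
    def __init__(self, report: "InclusionReport"):
        super().__init__(f"dataset failed inclusion: {report.reasons}")
        self.report = report


@dataclass
class InclusionReport:
    passed: bool
    reasons: list = field(default_factory=list)
    fraction_missing: dict = field(default_factory=dict)
    total_span_days: float = 0.0
    max_gap_hours: float = 0.0
    first_day_gap: bool = False


# ---------------------------------------------------------------------------
# interval helpers


def in_intervals(t: np.ndarray, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean mask: which times fall inside any half-open [start, end)."""
    t = np.asarray(t, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    for start, end in intervals:
        mask |= (t >= start) & (t < end)
    return mask


def mask_to_intervals(t: np.ndarray, mask: np.ndarray, cadence: float) -> list[tuple[float, float]]:
    """Convert a per-sample boolean mask to merged [start, end) intervals."""
    out: list[tuple[float, float]] = []
    for s, e in _runs(np.asarray(mask, dtype=bool)):
        start, end = float(t[s]), float(t[e - 1]) + cadence
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# cleaning


def clean_temperature(
    series: ChannelSeries,
    removal_intervals: Sequence[tuple[float, float]] = (),
    off_wrist_intervals: Sequence[tuple[float, float]] = (),
) -> ChannelSeries:
    """Apply the temperature exclusion rules, preserving the time grid.

    Order: logged-removal / off-wrist exclusion, then the 20 °C floor, then
    the 3-SD outlier rule computed on the remaining samples.
    """
    if series.values.size == 0:
        raise EmptyChannelError("empty temperature series")
    out = series.copy()
    v = out.values
    excl = in_intervals(out.timestamps, list(removal_intervals) + list(off_wrist_intervals))
    v[excl] = np.nan
    v[v < TEMP_FLOOR_C] = np.nan
    ok = ~np.isnan(v)
    if ok.sum() >= 2:
        mu, sd = float(np.mean(v[ok])), float(np.std(v[ok]))
        if sd > 0:
            v[np.abs(v - mu) > TEMP_OUTLIER_SD * sd] = np.nan
    if np.isnan(v).all():
        raise EmptyChannelError("temperature cleaning removed all samples")
    return out


def average_bilateral(sensors: Iterable[ChannelSeries]) -> list[ChannelSeries]:
    """Average left/right sensors per site; midline sternum passes through.

    When one side is missing at a time point the available side is used.
    All sensors must share a common time grid.
    """
    by_site: dict[str, list[ChannelSeries]] = {}
    for s in sensors:
        by_site.setdefault(s.site or "", []).append(s)
    out = []
    for site in sorted(by_site):
        group = by_site[site]
        if site == "sternum":
            if len(group) != 1:
                raise SchemaError("expected exactly one sternum sensor")
            out.append(group[0].copy())
            continue
        if site not in BILATERAL_SITES:
            raise SchemaError(f"unknown site pairing {site!r}")
        if len(group) > 2:
            raise SchemaError(f"more than two sensors for site {site!r}")
        t0 = group[0].timestamps
        for g in group[1:]:
            if g.timestamps.shape != t0.shape or not np.allclose(g.timestamps, t0):
                raise SchemaError(f"sensors for site {site!r} not on a common grid")
        stacked = np.vstack([g.values for g in group])
        with np.errstate(invalid="ignore"):
            merged = np.nanmean(stacked, axis=0)
        out.append(ChannelSeries(t0.copy(), merged, "temperature", site))
    return out


def detrend_scale_temperature(series: ChannelSeries) -> ChannelSeries:
    """Subtract a centred +/-12 h moving average, z-transform, drop |z| > 2.

    The moving average shrinks to the available samples near the edges; a
    zero-variance series z-transforms to zeros.
    """
    out = series.copy()
    half = int(round(720.0 / out.cadence))
    ma = (
        pd.Series(out.values)
        .rolling(window=2 * half + 1, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    d = out.values - ma
    mu = np.nanmean(d) if not np.isnan(d).all() else 0.0
    sd = np.nanstd(d) if not np.isnan(d).all() else 0.0
    if sd > 0:
        z = (d - mu) / sd
    else:
        z = np.zeros_like(d)
        z[np.isnan(d)] = np.nan
    z[np.abs(z) > DETREND_OUTLIER_SD] = np.nan
    out.values = z
    return out


def clean_light(
    epochs: pd.DataFrame,
    sleep: Sequence[SleepInterval],
    column: str = "blue",
) -> ChannelSeries:
    """Clean and log-transform a light channel from 1-min actigraphy epochs."""
    t = epochs["timestamp"].to_numpy(dtype=float)
    v = epochs[column].to_numpy(dtype=float).copy()
    off = epochs["off_wrist"].to_numpy(dtype=bool)
    asleep = in_intervals(t, [(s.onset, s.offset) for s in sleep])
    if asleep.all():
        raise ConfigurationError("no wake epochs; check sleep intervals")
    v[off] = np.nan
    wake_artifact = (~asleep) & (v < LIGHT_WAKE_ARTIFACT)
    v[wake_artifact] = np.nan
    ok = ~np.isnan(v)
    v[ok] = np.log10(np.maximum(v[ok], LIGHT_FLOOR))
    return ChannelSeries(t, v, "light")


def clean_activity(epochs: pd.DataFrame, column: str = "activity") -> ChannelSeries:
    """Clean an activity-count channel: off-wrist excluded, gaps interpolated,
    negatives clamped to 0, z-transformed, |z| > 2 removed."""
    t = epochs["timestamp"].to_numpy(dtype=float)
    v = epochs[column].to_numpy(dtype=float).copy()
    off = epochs["off_wrist"].to_numpy(dtype=bool)
    v[off] = np.nan
    series = ChannelSeries(t, v, "activity")
    if np.isnan(v).all():
        raise EmptyChannelError("activity cleaning removed all samples")
    if series.missing_mask.any():
        series = fill_gaps(series)
    w = series.values
    w[w < 0] = 0.0
    mu, sd = float(np.mean(w)), float(np.std(w))
    z = (w - mu) / sd if sd > 0 else np.zeros_like(w)
    z[np.abs(z) > ACTIVITY_OUTLIER_SD] = np.nan
    return ChannelSeries(series.timestamps, z, "activity")


# ---------------------------------------------------------------------------
# inclusion and gap filling


def check_inclusion(channels: Mapping[str, ChannelSeries]) -> InclusionReport:
    """Evaluate the three inclusion criteria over a set of cleaned channels."""
    reasons = []
    fracs = {}
    span_days = np.inf
    max_gap_h = 0.0
    first_day = False
    for name, ch in channels.items():
        fracs[name] = ch.fraction_missing
        if ch.fraction_missing >= MAX_MISSING_FRACTION:
            if "missing_fraction" not in reasons:
                reasons.append("missing_fraction")
        t = ch.timestamps
        span = (t[-1] - t[0] + ch.cadence) / 1440.0 if t.size >= 2 else 0.0
        span_days = min(span_days, span)
        for s, e in _runs(ch.missing_mask):
            gap_h = (e - s) * ch.cadence / 60.0
            max_gap_h = max(max_gap_h, gap_h)
            if gap_h >= FIRST_DAY_GAP_HOURS and t[s] < t[0] + 1440.0:
                first_day = True
    if span_days < MIN_SPAN_DAYS:
        reasons.append("min_span")
    if max_gap_h > MAX_GAP_HOURS:
        reasons.append("max_gap")
    return InclusionReport(
        passed=not reasons,
        reasons=reasons,
        fraction_missing=fracs,
        total_span_days=float(span_days) if np.isfinite(span_days) else 0.0,
        max_gap_hours=max_gap_h,
        first_day_gap=first_day,
    )


def _ar_forecast(segment: np.ndarray, order: int, steps: int) -> np.ndarray:
    """Recursive AR(order) forecast fitted on ``segment`` (no NaN)."""
    from statsmodels.tsa.ar_model import AutoReg

    n = segment.size
    p = int(max(1, min(order, n // 2 - 1)))
    if n < p + 5:
        raise ValueError("segment too short for AR fit")
    res = AutoReg(segment, lags=p, trend="c").fit()
    const, coefs = res.params[0], res.params[1:]
    hist = list(segment[-p:])
    out = np.empty(steps)
    for i in range(steps):
        x = const + float(np.dot(coefs, hist[::-1]))
        out[i] = x
        hist.append(x)
        hist.pop(0)
    mu, sd = float(np.mean(segment)), float(np.std(segment))
    if not np.all(np.isfinite(out)) or np.any(np.abs(out - mu) > 8.0 * sd + 1e-9):
        raise ValueError("unstable AR forecast")
    return out


def _contiguous_before(v: np.ndarray, idx: int, max_len: int | None = None) -> np.ndarray:
    """Longest non-missing run ending just before index ``idx``."""
    j = idx
    while j > 0 and not np.isnan(v[j - 1]):
        j -= 1
    seg = v[j:idx]
    if max_len is not None and seg.size > max_len:
        seg = seg[-max_len:]
    return seg


def fill_gaps(series: ChannelSeries) -> ChannelSeries:
    """Interpolate missing runs with blended forward/backward AR forecasts.

    Rules: a run of >= 3 h starting within the first day of the (current)
    recording truncates the series to the end of that run; runs of <= 1 h use
    an AR model of order min(50, n/4) fitted on the history; longer runs use
    at most one day of history with order equal to half a day of samples.
    When an AR fit is impossible or unstable the gap is filled by linear
    interpolation, with a warning. The output has no missing values.
    """
    t = series.timestamps.copy()
    v = series.values.copy()
    cad = series.cadence
    if v.size == 0:
        raise EmptyChannelError("empty series")
    if not np.isnan(v).any():
        return series.copy()

    # trim leading/trailing missing samples (nothing to anchor a forecast on)
    ok = np.flatnonzero(~np.isnan(v))
    if ok.size == 0:
        raise EmptyChannelError("all samples missing")
    t, v = t[ok[0]: ok[-1] + 1], v[ok[0]: ok[-1] + 1]

    # first-day truncation (re-checked against the post-truncation start)
    while True:
        runs = _runs(np.isnan(v))
        trunc = None
        for s, e in runs:
            if (e - s) * cad >= FIRST_DAY_GAP_HOURS * 60.0 and t[s] < t[0] + 1440.0:
                trunc = e
                break
        if trunc is None:
            break
        logger.warning("fill_gaps: first-day gap, truncating %d samples", trunc)
        t, v = t[trunc:], v[trunc:]
        if v.size == 0:
            raise EmptyChannelError("first-day truncation removed all samples")

    samples_per_day = int(round(1440.0 / cad))
    half_day = int(round(720.0 / cad))
    for s, e in _runs(np.isnan(v)):
        steps = e - s
        gap_min = steps * cad
        if gap_min <= SHORT_GAP_HOURS * 60.0:
            before = _contiguous_before(v, s)
            order = min(50, max(1, before.size // 4))
        else:
            before = _contiguous_before(v, s, max_len=samples_per_day)
            order = half_day
        filled = None
        try:
            fwd = _ar_forecast(before, order, steps)
            after_rev = _contiguous_before(v[::-1], v.size - e,
                                           max_len=None if gap_min <= 60 else samples_per_day)
            try:
                bwd = _ar_forecast(after_rev, order, steps)[::-1]
                w = np.linspace(0.0, 1.0, steps + 2)[1:-1]
                filled = (1.0 - w) * fwd + w * bwd
            except ValueError:
                filled = fwd
        except ValueError:
            filled = None
        if filled is None:
            logger.warning(
                "fill_gaps: AR fill unavailable for %.0f-min gap, using linear interpolation",
                gap_min,
            )
            left = v[s - 1] if s > 0 else v[e]
            right = v[e] if e < v.size else v[s - 1]
            filled = left + (right - left) * np.arange(1, steps + 1) / (steps + 1)
        v[s:e] = filled
    return ChannelSeries(t, v, series.channel_kind, series.site)


# ---------------------------------------------------------------------------
# binning and alignment


def bin_channel(series: ChannelSeries, bin_minutes: int = 30) -> pd.Series:
    """Per-bin arithmetic means; only bins with full sample coverage kept."""
    t, v = series.timestamps, series.values
    cad = series.cadence
    per_bin = int(round(bin_minutes / cad))
    idx = np.floor(t / bin_minutes).astype(int)
    frame = pd.DataFrame({"bin": idx, "v": v})
    g = frame.groupby("bin")["v"]
    counts = g.count()
    means = g.mean()
    full = counts[counts == per_bin].index
    means = means.loc[full]
    centers = means.index.to_numpy(dtype=float) * bin_minutes + bin_minutes / 2.0
    return pd.Series(means.to_numpy(), index=centers)


def bin_align(
    channels: Mapping[str, ChannelSeries],
    bin_minutes: int = 30,
    min_days: float = 1.0,
) -> BinnedMatrix:
    """Bin every channel and trim all columns to the common overlapping span.

    Bins start on the hour or half hour with the timestamp at the bin centre;
    matrices whose aligned span is shorter than ``min_days`` are rejected.
    """
    binned = {name: bin_channel(ch, bin_minutes) for name, ch in channels.items()}
    lo = max(s.index.min() for s in binned.values())
    hi = min(s.index.max() for s in binned.values())
    if not lo <= hi:
        raise AlignmentError("channels do not overlap")
    frame = pd.DataFrame({name: s.loc[(s.index >= lo) & (s.index <= hi)]
                          for name, s in binned.items()})
    frame = frame.dropna()
    span_days = len(frame) * bin_minutes / 1440.0
    if span_days < min_days:
        raise AlignmentError(
            f"aligned span {span_days:.2f} days below minimum length of {min_days} day(s)"
        )
    frame.index.name = "bin_center"
    return BinnedMatrix(frame)
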