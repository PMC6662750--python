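"""Phase estimation from predicted rhythms, error scoring, comparators.

Signed prediction error is measured minus predicted, wrapped to the nearest
cycle; summaries mirror the published error-table columns. The circular
association between measured and predicted phase vectors uses the
Jammalamadaka-SenGupta correlation coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    MINUTES_PER_DAY,
    PhaseEstimate,
    SleepInterval,
    circular_mean_minutes,
    wrap_minutes,
)
from .reference import (
    ExcretionSeries,
    FitError,
    center_of_gravity,
    fit_bsbcf,
    fit_cosine,
    measured_phase_from_fit,
)

logger = logging.getLogger("circaphase")

WITHIN_WINDOWS = (15, 30, 60, 120)


class PairingError(ValueError):
    pass


@dataclass
class ErrorSummary:
    """Summary statistics of signed phase errors (minutes)."""

    n: int
    mean: float
    median: float
    SD: float
    MAE: float
    medianAE: float
    SD_AE: float
    min_AE: float
    max_AE: float
    RMSE: float
    pct_within: dict
    circular_r: float = np.nan
    circular_p: float = np.nan

    def as_row(self) -> dict:
        row = {
            "n": self.n, "mean": self.mean, "median": self.median, "SD": self.SD,
            "MAE": self.MAE, "medianAE": self.medianAE, "SD_AE": self.SD_AE,
            "min_AE": self.min_AE, "max_AE": self.max_AE, "RMSE": self.RMSE,
            "r": self.circular_r, "p": self.circular_p,
        }
        for w in WITHIN_WINDOWS:
            row[f"pct_within_{w}"] = self.pct_within[w]
        return row


@dataclass
class PhaseAngle:
    """Signed time difference (hours) between a behavioural anchor and an
    acrophase; negative when sleep onset precedes the acrophase."""

    value: float
    reference: str = "sleep onset"


def predicted_phase(times: np.ndarray, values: np.ndarray, source: str,
                    low_amplitude_threshold: float = 0.01) -> PhaseEstimate:
    """Phase of a predicted rhythm: fit the marker's curve, then take its CoG.

    BSBCF for melatonin-trained networks, 24-h cosine for aMT6s. A fitted
    amplitude below ``low_amplitude_threshold`` (on the [0, 1] predicted
    scale) raises a ``low_amplitude`` flag instead of failing.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times[-1] - times[0] < MINUTES_PER_DAY:
        raise FitError("predicted rhythm must span at least 24 h")
    if source == "melatonin":
        fit = fit_bsbcf(times, values)
        amplitude = fit.params.H
    else:
        fit = fit_cosine(ExcretionSeries(times, values))
        amplitude = fit.params.a
    flags = ()
    if amplitude < low_amplitude_threshold or fit.degenerate:
        flags = ("low_amplitude",)
    est = measured_phase_from_fit(fit.params, marker=source)
    return PhaseEstimate(est.clock_time, method="network", marker=source,
                         date=est.date, flags=flags)


def phase_error(measured: PhaseEstimate, predicted: PhaseEstimate) -> float:
    """Signed error in minutes: measured minus predicted, wrapped to
    (-720, +720]."""
    if measured.marker != predicted.marker:
        raise PairingError(
            f"marker mismatch: {measured.marker} vs {predicted.marker}")
    if (measured.date is not None and predicted.date is not None
            and measured.date != predicted.date):
        raise PairingError(f"date mismatch: {measured.date} vs {predicted.date}")
    return float(wrap_minutes(measured.clock_time - predicted.clock_time))


def summarize(errors: Sequence[float],
              measured: Optional[Sequence[float]] = None,
              predicted: Optional[Sequence[float]] = None) -> ErrorSummary:
    """All error-table columns; circular correlation included when the
    measured/predicted clock-time vectors are supplied."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one error")
    ae = np.abs(e)
    r = p = np.nan
    if measured is not None and predicted is not None and len(measured) >= 3:
        r, p = circular_correlation(measured, predicted)
    return ErrorSummary(
        n=int(e.size),
        mean=float(np.mean(e)),
        median=float(np.median(e)),
        SD=float(np.std(e, ddof=1)) if e.size > 1 else 0.0,
        MAE=float(np.mean(ae)),
        medianAE=float(np.median(ae)),
        SD_AE=float(np.std(ae, ddof=1)) if e.size > 1 else 0.0,
        min_AE=float(np.min(ae)),
        max_AE=float(np.max(ae)),
        RMSE=float(np.sqrt(np.mean(e ** 2))),
        pct_within={w: float(np.mean(ae <= w) * 100.0) for w in WITHIN_WINDOWS},
        circular_r=r,
        circular_p=p,
    )


def circular_correlation(a_minutes: Sequence[float],
                         b_minutes: Sequence[float]) -> tuple[float, float]:
    """Jammalamadaka-SenGupta circular correlation of two clock-time vectors,
    with the large-sample normal p-value. Degenerate (zero-spread) inputs
    return (nan, nan) with a warning."""
    a = 2.0 * np.pi * np.asarray(a_minutes, dtype=float) / MINUTES_PER_DAY
    b = 2.0 * np.pi * np.asarray(b_minutes, dtype=float) / MINUTES_PER_DAY
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors of >= 3 phases")
    abar = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    bbar = np.arctan2(np.sin(b).mean(), np.cos(b).mean())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt(np.sum(sa ** 2) * np.sum(sb ** 2))
    if denom <= 1e-9:  # zero resultant spread up to rounding
        warnings.warn("circular correlation undefined for zero-spread input")
        return np.nan, np.nan
    r = float(np.sum(sa * sb) / denom)
    n = a.size
    l20, l02 = np.mean(sa ** 2), np.mean(sb ** 2)
    l22 = np.mean(sa ** 2 * sb ** 2)
    if l22 <= 0:
        return r, np.nan
    z = np.sqrt(n * l20 * l02 / l22) * r
    p = float(2.0 * (1.0 - stats.norm.cdf(abs(z))))
    return r, p


def midsleep_proxy(sleep: Sequence[SleepInterval],
                   marker: str = "aMT6s") -> PhaseEstimate:
    """Circular mean of per-sleep midpoints as a phase proxy."""
    if not sleep:
        raise ValueError("no sleep intervals")
    mids = [s.midpoint % MINUTES_PER_DAY for s in sleep]
    return PhaseEstimate(circular_mean_minutes(mids), method="mid-sleep", marker=marker)


def range_guess(rng: np.random.Generator, marker: str = "aMT6s") -> PhaseEstimate:
    """Uniform draw over the 1.3-7.1 h acrophase range reported for sighted,
    normally entrained individuals."""
    hours = rng.uniform(1.3, 7.1)
    return PhaseEstimate(hours * 60.0, method="normal-range guess", marker=marker)


def resample_guess(group_phases: Sequence[float], self_index: int,
                   rng: np.random.Generator, marker: str = "aMT6s") -> PhaseEstimate:
    """Draw uniformly from the other participants' measured acrophases."""
    if len(group_phases) < 2:
        raise ValueError("resampling guess needs a group of >= 2 measured phases")
    others = [ph for i, ph in enumerate(group_phases) if i != self_index]
    return PhaseEstimate(others[rng.integers(len(others))],
                         method="resampling guess", marker=marker)


def phase_angle(acrophase: PhaseEstimate, mean_sleep_onset: float) -> PhaseAngle:
    """Signed circular difference (hours) between average sleep onset and the
    acrophase; negative when onset precedes the acrophase."""
    diff = wrap_minutes(mean_sleep_onset - acrophase.clock_time)
    return PhaseAngle(float(diff) / 60.0, reference="sleep onset")
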