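"""Reference circadian target waveforms and measured phase.

Melatonin profiles are fitted with a bimodal skewed baseline cosine function
(BSBCF); urinary aMT6s excretion rates with a 24-h cosine. The fitted curve
is tiled over the ambulatory span (optionally with a drifting period), scaled
to [0, 1], and optionally perturbed with Gaussian noise. Phase is the centre
of gravity (CoG) of the above-baseline portion of one 24-h cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .datatypes import MINUTES_PER_DAY, PhaseEstimate

logger = logging.getLogger("circaphase")

TWO_PI = 2.0 * np.pi
RAD_PER_MIN = TWO_PI / MINUTES_PER_DAY


class FitError(RuntimeError):
    pass


class UndefinedPhaseError(ValueError):
    pass


class ImplausibleDriftError(ValueError):
    pass


@dataclass
class BSBCFParams:
    """Parameters of the bimodal skewed baseline cosine function.

    Bounds: b > 0 (baseline), H > 0 (peak height), -1 <= c < 1 (peak width),
    0 <= m < 1 (bimodality), 0 <= phi <= 2*pi (phase, radians), -5 <= v <= 5
    (skewness).
    """

    b: float
    H: float
    c: float
    m: float
    phi: float
    v: float

    def validate(self) -> None:
        if not (self.b > 0 and self.H > 0):
            raise ValueError("b and H must be positive")
        if not (-1.0 <= self.c < 1.0):
            raise ValueError("c out of [-1, 1)")
        if not (0.0 <= self.m < 1.0):
            raise ValueError("m out of [0, 1)")
        if not (0.0 <= self.phi <= TWO_PI):
            raise ValueError("phi out of [0, 2pi]")
        if not (-5.0 <= self.v <= 5.0):
            raise ValueError("v out of [-5, 5]")

    @property
    def phase_minutes(self) -> float:
        return float(self.phi / RAD_PER_MIN % MINUTES_PER_DAY)


@dataclass
class CosineParams:
    """24-h cosine parameters: amplitude a, baseline b, phase offset phi
    (minutes past midnight, the acrophase)."""

    a: float
    b: float
    phi: float

    def validate(self) -> None:
        if not (0.0 < self.a < 10000.0):
            raise ValueError("a out of (0, 10000)")
        if not (0.0 < self.b < 10000.0):
            raise ValueError("b out of (0, 10000)")
        if not (0.0 <= self.phi < MINUTES_PER_DAY):
            raise ValueError("phi out of [0, 1440)")


@dataclass
class ExcretionSeries:
    midpoint_times: np.ndarray  # minutes
    rates: np.ndarray  # ng / hour


@dataclass
class ReferenceWaveform:
    """1-min resolution target rhythm over the ambulatory span.

    ``values`` are scaled to [0, 1] before optional additive noise;
    ``baseline_scaled`` is the fitted baseline on the scaled axis.
    """

    timestamps: np.ndarray
    values: np.ndarray
    baseline_scaled: float
    source: str  # melatonin | aMT6s
    measured_phase: PhaseEstimate
    drift_per_day: float = 0.0  # hours/day; 0 for a stable rhythm

    def value_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.timestamps, self.values)


# ---------------------------------------------------------------------------
# waveform evaluation


def bsbcf(t: np.ndarray | float, p: BSBCFParams) -> np.ndarray | float:
    """Evaluate the bimodal skewed baseline cosine function at time ``t``
    (radians, 2*pi = 24 h)."""
    t = np.asarray(t, dtype=float)
    if p.c >= 1.0:
        raise ZeroDivisionError("c = 1 is outside the admissible bounds")
    d = t - p.phi
    x = np.cos(d + p.v * np.cos(d)) + p.m * np.cos(2.0 * t - 2.0 * p.phi - np.pi) - p.c
    out = p.b + p.H / (2.0 * (1.0 - p.c)) * (x + np.abs(x))
    return out if out.ndim else float(out)


def cosine24(t_minutes: np.ndarray | float, p: CosineParams) -> np.ndarray | float:
    """Evaluate the 24-h cosine at time ``t_minutes``."""
    t = np.asarray(t_minutes, dtype=float)
    out = p.b + p.a * np.cos(RAD_PER_MIN * (t - p.phi))
    return out if out.ndim else float(out)


def _curve_values(params, t_minutes: np.ndarray, period: float = MINUTES_PER_DAY,
                  anchor: float = 0.0) -> np.ndarray:
    """Evaluate either fitted curve on a minute grid, optionally time-warped
    to a non-24-h period. ``anchor`` is an absolute time (minutes) at which
    the warped curve agrees in phase with the unwarped one."""
    t = np.asarray(t_minutes, dtype=float)
    warped = anchor + (t - anchor) * (MINUTES_PER_DAY / period)
    if isinstance(params, BSBCFParams):
        return np.asarray(bsbcf(warped * RAD_PER_MIN, params))
    return np.asarray(cosine24(warped, params))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    params: object  # BSBCFParams | CosineParams
    sse: float
    degenerate: bool = False


def fit_bsbcf(times_minutes: np.ndarray, concentrations: np.ndarray,
              n_phase_starts: int = 8, resample: bool = False) -> FitResult:
    """Nonlinear least-squares BSBCF fit to a melatonin profile.

    The time vector is converted to radians (2*pi = 24 h) and the period
    fixed at 24 h. Multiple starts over a uniform phase grid are tried and
    the best-residual fit returned.

    ``resample=True`` first linearly interpolates the profile to 1-min
    epochs (the original processing); the default fits the raw sample times,
    because the interpolated polyline systematically differs from the curve
    and biases the recovered shape parameters on sparsely sampled profiles.
    For equally spaced samples the two differ only by that polyline bias.
    """
    times = np.asarray(times_minutes, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if times.size < 3 or times[-1] - times[0] < MINUTES_PER_DAY:
        raise FitError("need at least 24 h of melatonin samples")
    if resample:
        grid = np.arange(times[0], times[-1] + 0.5, 1.0)
        y = np.interp(grid, times, conc)
    else:
        grid, y = times, conc
    t_rad = grid * RAD_PER_MIN

    lo = float(np.quantile(y, 0.1))
    b0 = max(lo, 1e-3)
    H0 = max(float(np.max(y)) - lo, 1e-3)
    eps = 1e-9
    bounds = (
        np.array([eps, eps, -1.0, 0.0, 0.0, -5.0]),
        np.array([np.inf, np.inf, 1.0 - 1e-6, 1.0 - 1e-6, TWO_PI, 5.0]),
    )

    def resid(theta):
        p = BSBCFParams(*theta)
        return bsbcf(t_rad, p) - y

    best = None
    for k, phi0 in enumerate(np.linspace(0.0, TWO_PI, n_phase_starts, endpoint=False)):
        x0 = np.array([b0, H0, 0.0, 0.0, phi0, 0.0])
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            sol = least_squares(resid, x0, bounds=bounds, method="trf", max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        sse = float(np.sum(sol.fun ** 2))
        if np.isfinite(sse) and (best is None or sse < best[0] - 1e-12):
            best = (sse, sol.x)
    if best is None:
        raise FitError("BSBCF fit failed from every start")
    sse, theta = best
    params = BSBCFParams(*[float(x) for x in theta])
    params.validate()
    data_range = float(np.max(y) - np.min(y))
    degenerate = params.H < max(0.05 * max(data_range, params.b), 1e-6) or data_range < 1e-9
    return FitResult(params, sse, degenerate)


def compute_excretion_rate(blocks) -> ExcretionSeries:
    """aMT6s excretion rate per urine block: concentration x volume / duration,
    timestamped at the interval midpoint."""
    mids, rates = [], []
    for blk in blocks:
        if blk.duration_hours <= 0:
            raise ValueError("zero-duration urine block")
        if blk.volume == 0:
            logger.warning("urine block at %.0f min has zero volume; rate set to 0", blk.start)
        mids.append(0.5 * (blk.start + blk.end))
        rates.append(blk.concentration * blk.volume / blk.duration_hours)
    return ExcretionSeries(np.asarray(mids, dtype=float), np.asarray(rates, dtype=float))


def fit_cosine(excretion: ExcretionSeries, n_phase_starts: int = 8) -> FitResult:
    """Nonlinear least-squares 24-h cosine fit to excretion rates.

    Starting values a=300, b=500, phi=24 (the published initialisation,
    reading the second symbol as the baseline), plus a uniform phase grid;
    the best-residual fit is returned. The acrophase is the fitted phi.
    """
    t = np.asarray(excretion.midpoint_times, dtype=float)
    r = np.asarray(excretion.rates, dtype=float)
    if t.size < 5 or t[-1] - t[0] < MINUTES_PER_DAY:
        raise FitError("need >= 5 excretion rates spanning >= 24 h")

    lb = np.array([1e-9, 1e-9, -np.inf])
    ub = np.array([1e4, 1e4, np.inf])

    def resid(theta):
        return cosine24(t, CosineParams(*theta)) - r

    starts = [np.array([300.0, 500.0, 24.0])]
    a0 = max(float(np.ptp(r)) / 2.0, 1e-6)
    b0 = min(max(float(np.mean(r)), 1e-6), 9999.0)
    starts += [np.array([a0, b0, phi0])
               for phi0 in np.linspace(0.0, MINUTES_PER_DAY, n_phase_starts, endpoint=False)]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", max_nfev=2000)
        except Exception:  # pragma: no cover
            continue
        sse = float(np.sum(sol.fun ** 2))
        if np.isfinite(sse) and (best is None or sse < best[0] - 1e-12):
            best = (sse, sol.x)
    if best is None:
        raise FitError("cosine fit failed from every start")
    sse, theta = best
    params = CosineParams(float(theta[0]), float(theta[1]),
                          float(theta[2]) % MINUTES_PER_DAY)
    params.validate()
    degenerate = params.a < max(0.05 * params.b, 1e-6) and float(np.ptp(r)) < 0.2 * params.b
    return FitResult(params, sse, degenerate)


# ---------------------------------------------------------------------------
# phase


def center_of_gravity(times_minutes: np.ndarray, values: np.ndarray, baseline: float,
                      method: str = "measured", marker: str = "melatonin") -> PhaseEstimate:
    """Centre of gravity of a 24-h, 1-min profile: sum t*(f-b) / sum (f-b).

    The caller supplies the window (starting at the waveform minimum for
    aMT6s, or at the first sustained increase above baseline for melatonin).
    """
    t = np.asarray(times_minutes, dtype=float)
    w = np.asarray(values, dtype=float) - baseline
    denom = float(np.sum(w))
    if denom <= 0:
        raise UndefinedPhaseError("waveform does not exceed baseline over the window")
    cog = float(np.sum(t * w) / denom)
    return PhaseEstimate(clock_time=cog % MINUTES_PER_DAY, method=method, marker=marker)


def window_start(params, search_from: float = 0.0) -> float:
    """Start of the 24-h phase window for a fitted curve (absolute minutes).

    Cosine: the fitted minimum (phi + 12 h). BSBCF: the first 1-min sample
    exceeding b + 2% of H sustained for 10 minutes, searched from the curve
    minimum.
    """
    if isinstance(params, CosineParams):
        start = (params.phi + 720.0) % MINUTES_PER_DAY
        while start < search_from:
            start += MINUTES_PER_DAY
        return start
    grid = np.arange(search_from, search_from + 2.0 * MINUTES_PER_DAY, 1.0)
    f = np.asarray(bsbcf(grid * RAD_PER_MIN, params))
    # search from the profile minimum so "first increase" is well defined
    i0 = int(np.argmin(f[: int(MINUTES_PER_DAY)]))
    thr = params.b + 0.02 * params.H
    above = f > thr
    run = 0
    for i in range(i0, grid.size):
        run = run + 1 if above[i] else 0
        if run >= 10:
            return float(grid[i - 9])
    raise UndefinedPhaseError("no sustained increase above baseline found")


def measured_phase_from_fit(params, marker: str) -> PhaseEstimate:
    """CoG phase of the fitted curve over one 24-h window.

    For the BSBCF the baseline is the fitted ``b`` (the curve floor). For
    the cosine, subtracting ``b`` leaves a zero-integral waveform whose CoG
    is undefined, so the curve minimum ``b - a`` is used instead; by
    symmetry the CoG then equals the fitted acrophase.
    """
    start = window_start(params)
    t = np.arange(start, start + MINUTES_PER_DAY, 1.0)
    vals = _curve_values(params, t)
    baseline = params.b - params.a if isinstance(params, CosineParams) else params.b
    return center_of_gravity(t, vals, baseline, method="measured", marker=marker)


# ---------------------------------------------------------------------------
# reference construction


def _with_phase(params, clock_minutes: float):
    """Copy of fitted params with the phase replaced by a clock time."""
    if isinstance(params, BSBCFParams):
        return BSBCFParams(params.b, params.H, params.c, params.m,
                           (clock_minutes % MINUTES_PER_DAY) * RAD_PER_MIN, params.v)
    return CosineParams(params.a, params.b, clock_minutes % MINUTES_PER_DAY)


def build_reference(
    fit: FitResult | object,
    span: tuple[float, float],
    source: str,
    second_acrophase: Optional[tuple[float, float]] = None,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ReferenceWaveform:
    """Tile the fitted curve over the ambulatory span as a [0, 1] target.

    Stable mode (no ``second_acrophase``) extrapolates the 24-h profile
    backwards over ``span``. Drifting mode takes ``second_acrophase =
    (clock_minutes, days_after_first)`` from a later assessment and
    regenerates the waveform with period 24 h plus the daily shift between
    the two acrophase times, anchored so the acrophase is correct at the
    second assessment (placed on the final day of the span). Pre-noise
    values are min-max scaled to [0, 1]; Gaussian noise of SD ``noise_sd``
    is then added from ``rng``.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    t0, t1 = span
    t = np.arange(t0, t1 + 0.5, 1.0)
    first_clock = (params.phase_minutes if isinstance(params, BSBCFParams)
                   else params.phi)

    drift_per_day = 0.0
    period = MINUTES_PER_DAY
    eval_params = params
    anchor = 0.0
    if second_acrophase is not None:
        clock2, n_days = second_acrophase
        if n_days < 1:
            raise ValueError("second acrophase must be at least one day after the first")
        shift_per_day = (((clock2 - first_clock) + 720.0) % MINUTES_PER_DAY - 720.0) / n_days
        if abs(shift_per_day) > 720.0:
            raise ImplausibleDriftError("daily drift exceeds 12 h/day")
        drift_per_day = shift_per_day / 60.0
        period = MINUTES_PER_DAY + shift_per_day
        eval_params = _with_phase(params, clock2)
        # place the second assessment's acrophase on the final day of the span
        anchor = np.floor(t1 / MINUTES_PER_DAY) * MINUTES_PER_DAY + (clock2 % MINUTES_PER_DAY)

    vals = _curve_values(eval_params, t, period=period, anchor=anchor)
    # scale using one full period of the unwarped curve so min -> 0, max -> 1
    ref_vals = _curve_values(eval_params, np.arange(0.0, MINUTES_PER_DAY, 1.0))
    mn, mx = float(np.min(ref_vals)), float(np.max(ref_vals))
    if mx - mn <= 0:
        raise UndefinedPhaseError("flat fitted curve cannot define a reference")
    scaled = (vals - mn) / (mx - mn)
    baseline_scaled = (params.b - mn) / (mx - mn)

    measured = measured_phase_from_fit(eval_params, marker=source)

    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        scaled = scaled + rng.normal(0.0, noise_sd, size=scaled.shape)

    return ReferenceWaveform(
        timestamps=t,
        values=scaled,
        baseline_scaled=baseline_scaled,
        source=source,
        measured_phase=measured,
        drift_per_day=drift_per_day,
    )
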