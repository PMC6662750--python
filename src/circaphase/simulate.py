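"""Synthetic cohorts with known ground-truth circadian phase.

Generators emulate the four schedule regimes (fixed 8:16, habitual, rotating
day-shift, night-shift) with configurable phase-to-schedule coupling, target
rhythms whose acrophase equals the injected true phase by construction,
masking, artefacts and missingness. All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import MINUTES_PER_DAY, Participant, SleepInterval, UrineBlock
from .preprocess import _runs, in_intervals
from .reference import RAD_PER_MIN, BSBCFParams, bsbcf

TWO_PI = 2.0 * np.pi


@dataclass
class SimConfig:
    """Cohort generator configuration (defaults are calibrated to the
    published fixed-sleep cohort characteristics)."""

    n_participants: int = 16
    schedule_type: str = "FS"  # FS | HS | SWday | SWnight
    n_days: int = 4
    true_phase_mean: float = 3.7  # acrophase clock time, hours
    true_phase_sd: float = 1.2
    drift_per_day: float = 0.0  # hours/day
    phase_angle_hours: float = 4.43  # sleep onset precedes acrophase by this
    coupling: float = 1.0  # 1 = schedule locked to phase, 0 = independent
    # schedule
    free_onset_hour: float = 23.3  # diurnal onset when decoupled
    hs_onset_jitter_hours: float = 0.75
    night_onset_mean: float = 9.56
    night_onset_sd: float = 1.0
    night_sleep_hours: float = 5.5
    inlab_days: int = 0  # final days flagged in-lab
    # light
    light_day_level: float = 50.0
    light_night_level: float = 0.005
    light_noise_sd: float = 0.0  # lognormal sigma
    # temperature
    n_temp_sites: int = 1  # 1 (wrist) or 11
    temp_baseline: float = 33.0
    temp_circadian_amplitude: float = 1.0
    temp_masking_amplitude: float = 0.0
    temp_noise_sd: float = 0.0
    # activity
    activity_day_mean: float = 250.0
    # melatonin profile (BSBCF shape)
    with_melatonin: bool = True
    mel_baseline: float = 2.0
    mel_peak: float = 50.0
    mel_width: float = 0.3
    mel_bimodality: float = 0.1
    mel_skew: float = 1.0
    mel_noise_sd: float = 0.0  # multiplicative (lognormal sigma)
    # urine collection
    urine_hours: float = 48.0
    amt6s_amplitude: float = 500.0
    amt6s_baseline: float = 600.0
    # corruption
    missing_fraction: float = 0.0
    inject_artifacts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_fraction < 0.5):
            raise ValueError("missing_fraction must be in [0, 0.5)")
        if self.schedule_type not in ("FS", "HS", "SWday", "SWnight"):
            raise ValueError(f"unknown schedule_type {self.schedule_type!r}")
        if self.n_temp_sites not in (1, 11):
            raise ValueError("n_temp_sites must be 1 or 11")


@dataclass
class SimParticipant:
    id: str
    true_acrophase_hours: float  # clock time of the day-0 acrophase
    schedule_type: str
    participant: Participant
    truth: dict = field(default_factory=dict)


def _period_minutes(cfg: SimConfig) -> float:
    return MINUTES_PER_DAY + cfg.drift_per_day * 60.0


def gen_schedule(schedule_type: str, cfg: SimConfig, rng: np.random.Generator,
                 true_phase_h: float) -> tuple[list[SleepInterval], list]:
    """Sleep intervals over the recording, plus in-lab intervals.

    Diurnal onsets blend the phase-coupled time (acrophase minus the phase
    angle) with a free-running default according to ``cfg.coupling``;
    night-shift daytime sleep is drawn independently of phase.
    """
    span = cfg.n_days * MINUTES_PER_DAY
    coupled = (true_phase_h - cfg.phase_angle_hours) % 24.0
    sleeps: list[SleepInterval] = []
    for d in range(-1, cfg.n_days):
        if schedule_type == "SWnight":
            if d < 0:
                continue  # day sleepers have no pre-recording spillover
            free = float(np.clip(rng.normal(cfg.night_onset_mean, cfg.night_onset_sd),
                                 8.0, 12.0))
            onset_h = cfg.coupling * coupled + (1.0 - cfg.coupling) * free
            dur_h = cfg.night_sleep_hours + rng.normal(0.0, 0.3)
        else:
            onset_h = cfg.coupling * coupled + (1.0 - cfg.coupling) * cfg.free_onset_hour
            if schedule_type in ("HS", "SWday"):
                onset_h += rng.normal(0.0, cfg.hs_onset_jitter_hours
                                      if schedule_type == "HS" else 0.5)
            dur_h = 8.0
        onset = d * MINUTES_PER_DAY + (onset_h % 24.0) * 60.0
        offset = onset + dur_h * 60.0
        if offset <= 0 or onset >= span:
            continue
        in_lab = cfg.inlab_days > 0 and onset >= span - cfg.inlab_days * MINUTES_PER_DAY
        sleeps.append(SleepInterval(onset, offset, in_lab))
    inlab = []
    if cfg.inlab_days > 0:
        inlab = [(span - cfg.inlab_days * MINUTES_PER_DAY, span)]
    return sleeps, inlab


def _wake_fraction(asleep: np.ndarray) -> np.ndarray:
    """Position within each wake episode, in [0, 1]; 0 while asleep."""
    w = np.zeros(asleep.size)
    for s, e in _runs(~asleep):
        w[s:e] = np.linspace(0.0, 1.0, e - s)
    return w


def inject_missing_runs(values: np.ndarray, rng: np.random.Generator,
                        fraction: float, cadence: float,
                        protect_minutes: float = 1440.0,
                        run_minutes: tuple[float, float] = (5.0, 45.0)) -> int:
    """Set short random runs of ``values`` to NaN in place until roughly
    ``fraction`` of samples are missing; the first ``protect_minutes`` are
    left intact (so inclusion-rule truncation is not triggered). Returns the
    number of newly missing samples."""
    n = values.size
    target = int(round(fraction * n))
    first_ok = int(np.ceil(protect_minutes / cadence))
    injected = 0
    guard = 0
    while injected < target and guard < 10000:
        guard += 1
        length = int(rng.integers(max(1, int(run_minutes[0] / cadence)),
                                  max(2, int(run_minutes[1] / cadence)) + 1))
        start = int(rng.integers(first_ok, max(first_ok + 1, n - length)))
        seg = values[start:start + length]
        fresh = ~np.isnan(seg)
        injected += int(fresh.sum())
        seg[:] = np.nan
    return injected


def gen_light(sleep: Sequence[SleepInterval], cfg: SimConfig,
              rng: np.random.Generator, span: float) -> tuple[pd.DataFrame, dict]:
    """1-min actigraphy epochs: blue irradiance, white lux, activity counts,
    off-wrist flag; optional injected artefacts with a ground-truth record."""
    t = np.arange(0.0, span, 1.0)
    asleep = in_intervals(t, [(s.onset, s.offset) for s in sleep])
    shape = 0.25 + 1.5 * np.sin(np.pi * _wake_fraction(asleep)) ** 2
    noise = np.exp(rng.normal(0.0, cfg.light_noise_sd, t.size)) \
        if cfg.light_noise_sd > 0 else 1.0
    blue = np.where(asleep, cfg.light_night_level,
                    np.maximum(cfg.light_day_level * shape, 1.2)) * noise
    blue[~asleep] = np.maximum(blue[~asleep], 1.2)  # wake levels clear the 1-unit rule

    activity = np.where(asleep, rng.poisson(3.0, t.size),
                        rng.poisson(cfg.activity_day_mean, t.size) * (0.3 + shape))
    off_wrist = np.zeros(t.size, dtype=bool)
    truth = {"cover_artifact_idx": np.array([], dtype=int),
             "off_wrist_idx": np.array([], dtype=int)}

    if cfg.inject_artifacts:
        wake_idx = np.flatnonzero((~asleep) & (t >= MINUTES_PER_DAY))
        cover = rng.choice(wake_idx, size=min(30, wake_idx.size), replace=False)
        blue[cover] = 0.5
        truth["cover_artifact_idx"] = np.sort(cover)
        bouts = []
        for _ in range(2):
            start = int(rng.integers(int(MINUTES_PER_DAY), int(span - 60)))
            bouts.append(np.arange(start, start + 30))
        ow = np.unique(np.concatenate(bouts))
        off_wrist[ow] = True
        truth["off_wrist_idx"] = ow

    df = pd.DataFrame({
        "timestamp": t,
        "blue": blue,
        "white_lux": blue * 35.0,  # proportional surrogate for photopic lux
        "activity": activity.astype(float),
        "off_wrist": off_wrist,
    })
    if cfg.missing_fraction > 0:
        n_inj = inject_missing_runs(df["blue"].to_numpy(), rng,
                                    cfg.missing_fraction, 1.0)
        df["blue"] = df["blue"].to_numpy()
        truth["light_missing_injected"] = n_inj
    return df, truth


_SITE_OFFSETS = {"shoulder": -0.6, "sternum": -0.3, "wrist": 0.0,
                 "thigh": -0.4, "calf": 0.2, "foot": 0.4}


def gen_temperature(sleep: Sequence[SleepInterval], true_phase_h: float,
                    cfg: SimConfig, rng: np.random.Generator,
                    span: float) -> tuple[pd.DataFrame, dict]:
    """Skin-temperature sensor streams at 2.5-min cadence.

    Each sensor is baseline + a circadian cosine locked to the true phase +
    a sleep-masking rise + AR(1) noise; left/right pairs differ only by
    independent noise. Values are clipped to a 25-40 degC physiological band.
    """
    t = np.arange(0.0, span, 2.5)
    acro = true_phase_h * 60.0
    period = _period_minutes(cfg)
    circ = cfg.temp_circadian_amplitude * np.cos(TWO_PI * (t - acro) / period)
    asleep = in_intervals(t, [(s.onset, s.offset) for s in sleep]).astype(float)
    kernel = np.ones(13) / 13.0  # ~30-min smoothing of the masking step
    masking = cfg.temp_masking_amplitude * np.convolve(asleep, kernel, mode="same")

    if cfg.n_temp_sites == 1:
        sensors = [("wrist", "left")]
    else:
        sensors = [(site, side) for site in ("shoulder", "wrist", "thigh", "calf", "foot")
                   for side in ("left", "right")] + [("sternum", "none")]

    frames = []
    truth = {}
    for site, side in sensors:
        noise = np.zeros(t.size)
        if cfg.temp_noise_sd > 0:
            eps = rng.normal(0.0, cfg.temp_noise_sd, t.size)
            for i in range(1, t.size):
                eps[i] += 0.85 * eps[i - 1]
            noise = eps
        v = np.clip(cfg.temp_baseline + _SITE_OFFSETS[site] + circ + masking + noise,
                    25.0, 40.0)
        if cfg.missing_fraction > 0:
            truth[f"temp_{site}_{side}_missing"] = inject_missing_runs(
                v, rng, cfg.missing_fraction, 2.5)
        frames.append(pd.DataFrame({"timestamp": t, "value": v,
                                    "site": site, "side": side}))
    return pd.concat(frames, ignore_index=True), truth


def gen_melatonin_profile(true_phase_h: float, cfg: SimConfig,
                          rng: np.random.Generator, start: float) -> pd.DataFrame:
    """38 hourly salivary samples from a BSBCF with phase = true phase."""
    t = start + 60.0 * np.arange(38)
    p = BSBCFParams(cfg.mel_baseline, cfg.mel_peak, cfg.mel_width,
                    cfg.mel_bimodality, (true_phase_h * 60.0 * RAD_PER_MIN) % TWO_PI,
                    cfg.mel_skew)
    v = np.asarray(bsbcf(t * RAD_PER_MIN, p), dtype=float)
    if cfg.mel_noise_sd > 0:
        v = v * np.exp(rng.normal(0.0, cfg.mel_noise_sd, v.size))
    return pd.DataFrame({"timestamp": t, "value": v})


def _rate_integral(t1: float, t2: float, acro: float, period: float,
                   a: float, b: float) -> float:
    """Mass (ng) excreted between t1 and t2 minutes for a cosine rate
    b + a*cos(2*pi*(t - acro)/period) in ng/h."""
    k = TWO_PI / period
    return (b * (t2 - t1) + (a / k) * (np.sin(k * (t2 - acro)) - np.sin(k * (t1 - acro)))) / 60.0


def gen_urine_blocks(true_phase_h: float, sleep: Sequence[SleepInterval],
                     cfg: SimConfig, rng: np.random.Generator,
                     window: tuple[float, float]) -> list[UrineBlock]:
    """Sequential 4-h collection blocks (8 h over sleep) whose concentrations
    back-compute from the integral of the generating cosine rate."""
    acro = true_phase_h * 60.0
    period = _period_minutes(cfg)
    t0, t1 = window
    blocks = []
    cur = t0
    while cur + 240.0 <= t1 + 1e-9:
        over_sleep = any(s.onset <= cur < s.offset or cur <= s.onset < cur + 240.0
                         for s in sleep)
        dur = 480.0 if over_sleep else 240.0
        end = cur + dur
        if end > t1 + 1e-9:
            dur, end = 240.0, cur + 240.0
            if end > t1 + 1e-9:
                break
        mass = _rate_integral(cur, end, acro, period,
                              cfg.amt6s_amplitude, cfg.amt6s_baseline)
        volume = float(rng.uniform(120.0, 400.0))
        blocks.append(UrineBlock(cur, end, volume, max(mass, 0.0) / volume))
        cur = end
    return blocks


def gen_participant(cfg: SimConfig, rng: np.random.Generator,
                    pid: str) -> SimParticipant:
    true_phase = float(rng.normal(cfg.true_phase_mean, cfg.true_phase_sd)) % 24.0
    span = cfg.n_days * MINUTES_PER_DAY
    sleep, inlab = gen_schedule(cfg.schedule_type, cfg, rng, true_phase)
    act, light_truth = gen_light(sleep, cfg, rng, span)
    temp, temp_truth = gen_temperature(sleep, true_phase, cfg, rng, span)
    melatonin = gen_melatonin_profile(true_phase, cfg, rng, span + 120.0) \
        if cfg.with_melatonin else None
    urine = gen_urine_blocks(true_phase, sleep, cfg, rng,
                             (span - cfg.urine_hours * 60.0, span))
    participant = Participant(
        id=pid, actigraphy=act, temperature=temp, sleep=sleep, urine=urine,
        melatonin=melatonin, inlab=inlab, schedule=cfg.schedule_type,
    )
    truth = {"true_acrophase_hours": true_phase, **light_truth, **temp_truth}
    return SimParticipant(pid, true_phase, cfg.schedule_type, participant, truth)


def gen_cohort(cfg: SimConfig) -> list[SimParticipant]:
    """Generate ``cfg.n_participants`` subjects from per-participant seed
    substreams of the master seed."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)
    return [gen_participant(cfg, np.random.default_rng(children[i]), f"P{i:03d}")
            for i in range(cfg.n_participants)]


def artifact_fixture(seed: int = 0) -> SimParticipant:
    """A deterministic participant with exactly known injected artefacts,
    for filter-bookkeeping tests.

    Injections (recorded in ``truth``): 4 sub-20 degC temperature samples, a
    45-min temperature gap, 7 wake-time light values below 1 unit, one 30-min
    off-wrist bout, a 4-h light gap on day 3, and a 3.5-h light gap starting
    at hour 10 of day 1 (which must truncate the series to the gap end).
    """
    cfg = SimConfig(n_participants=1, n_days=4, coupling=1.0, seed=seed,
                    light_noise_sd=0.0, temp_noise_sd=0.0,
                    temp_masking_amplitude=0.0, temp_circadian_amplitude=0.5)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sim = gen_participant(cfg, rng, "FIXTURE")
    act = sim.participant.actigraphy
    t = act["timestamp"].to_numpy()
    asleep = in_intervals(t, [(s.onset, s.offset) for s in sim.participant.sleep])

    blue = act["blue"].to_numpy().copy()
    gap4_lo, gap4_hi = 2 * MINUTES_PER_DAY + 300, 2 * MINUTES_PER_DAY + 540
    wake_idx = np.flatnonzero(~asleep & (t >= 2 * MINUTES_PER_DAY)
                              & ((t < gap4_lo) | (t >= gap4_hi)))
    cover_idx = wake_idx[:: max(1, wake_idx.size // 7)][:7]
    blue[cover_idx] = 0.5
    off_idx = np.arange(int(3 * MINUTES_PER_DAY + 120), int(3 * MINUTES_PER_DAY + 150))
    off = act["off_wrist"].to_numpy().copy()
    off[off_idx] = True
    gap4_idx = np.arange(int(gap4_lo), int(gap4_hi))
    blue[gap4_idx] = np.nan
    first_day_gap_idx = np.arange(600, 810)  # 3.5 h starting at hour 10 of day 1
    blue[first_day_gap_idx] = np.nan
    act = act.assign(blue=blue, off_wrist=off)

    temp = sim.participant.temperature.copy()
    tv = temp["value"].to_numpy().copy()
    sub20_idx = np.array([700, 800, 900, 1000])
    tv[sub20_idx] = 19.0
    tgap_idx = np.arange(1200, 1218)  # 45 min at 2.5-min cadence
    tv[tgap_idx] = np.nan
    temp = temp.assign(value=tv)

    sim.participant.actigraphy = act
    sim.participant.temperature = temp
    sim.truth.update({
        "cover_artifact_idx": cover_idx,
        "off_wrist_idx": off_idx,
        "light_gap_idx": gap4_idx,
        "first_day_gap_idx": first_day_gap_idx,
        "first_day_gap_end_minute": 810.0,
        "sub20_idx": sub20_idx,
        "temp_gap_idx": tgap_idx,
    })
    return sim
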