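"""End-to-end orchestration: raw participant -> binned inputs -> reference
waveform -> lagged designs -> trained/validated model -> phase estimates."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig, substream
from .datatypes import BinnedMatrix, ChannelSeries, Participant, PhaseEstimate
from .evaluate import ErrorSummary, phase_error, predicted_phase, summarize
from .network import LaggedDesign, TrainedModel, build_lagged_design, loocv, train_final
from .preprocess import (
    ExclusionError,
    InclusionReport,
    average_bilateral,
    bin_align,
    check_inclusion,
    clean_activity,
    clean_light,
    clean_temperature,
    detrend_scale_temperature,
    fill_gaps,
    mask_to_intervals,
)
from .reference import (
    ReferenceWaveform,
    build_reference,
    compute_excretion_rate,
    fit_bsbcf,
    fit_cosine,
)

logger = logging.getLogger("circaphase")


def _temperature_channels(p: Participant, mode: str) -> list[ChannelSeries]:
    """Raw per-sensor temperature series from the participant table."""
    grouped = []
    for (site, side), sub in p.temperature.groupby(["site", "side"], sort=True):
        grouped.append(
            ChannelSeries(sub["timestamp"].to_numpy(dtype=float),
                          sub["value"].to_numpy(dtype=float), "temperature", site)
        )
        grouped[-1].side = side  # kept for bilateral pairing diagnostics
    if mode == "wrist":
        wrists = [g for g in grouped if g.site == "wrist"]
        if not wrists:
            raise ValueError(f"participant {p.id} has no wrist temperature sensor")
        return wrists[:1]
    return grouped


def preprocess_participant(
    p: Participant,
    config: RunConfig,
    temp_mode: str = "wrist",
    include_activity: bool = False,
) -> tuple[BinnedMatrix, InclusionReport]:
    """Clean, detrend, check inclusion, fill gaps, bin and align one
    participant's channels. Raises :class:`ExclusionError` when the cleaned
    channels fail the inclusion criteria."""
    act_t = p.actigraphy["timestamp"].to_numpy(dtype=float)
    off = p.actigraphy["off_wrist"].to_numpy(dtype=bool)
    off_intervals = mask_to_intervals(act_t, off, 1.0)

    channels: dict[str, ChannelSeries] = {}
    channels["light"] = clean_light(p.actigraphy, p.sleep)

    raw_temp = _temperature_channels(p, temp_mode)
    if temp_mode == "wrist":
        cleaned = clean_temperature(raw_temp[0], p.temp_removal_log, off_intervals)
        channels["temp_wrist"] = detrend_scale_temperature(cleaned)
    else:
        cleaned = [clean_temperature(s, p.temp_removal_log) for s in raw_temp]
        for merged in average_bilateral(cleaned):
            channels[f"temp_{merged.site}"] = detrend_scale_temperature(merged)

    if include_activity:
        channels["activity"] = clean_activity(p.actigraphy)

    report = check_inclusion(channels)
    if not report.passed:
        raise ExclusionError(report)
    filled = {name: fill_gaps(ch) for name, ch in channels.items()}
    binned = bin_align(filled, config.bin_minutes)
    return binned, report


def reference_for_participant(
    p: Participant,
    source: str,
    span: tuple[float, float],
    config: RunConfig,
    rng: Optional[np.random.Generator] = None,
) -> ReferenceWaveform:
    """Fit the marker-appropriate curve and tile it over ``span``."""
    if source == "melatonin":
        if p.melatonin is None:
            raise ValueError(f"participant {p.id} has no melatonin profile")
        fit = fit_bsbcf(p.melatonin["timestamp"].to_numpy(dtype=float),
                        p.melatonin["value"].to_numpy(dtype=float))
    elif source == "aMT6s":
        fit = fit_cosine(compute_excretion_rate(p.urine))
    else:
        raise ValueError(f"unknown reference source {source!r}")
    noise_sd = config.noise_sd if rng is not None else 0.0
    return build_reference(fit, span, source, noise_sd=noise_sd, rng=rng)


@dataclass
class CohortData:
    designs: list = field(default_factory=list)  # list[LaggedDesign]
    measured: dict = field(default_factory=dict)  # pid -> PhaseEstimate
    reports: dict = field(default_factory=dict)  # pid -> InclusionReport
    excluded: dict = field(default_factory=dict)  # pid -> InclusionReport


def prepare_cohort(
    cohort: Sequence[Participant],
    config: RunConfig,
    source: str = "aMT6s",
    temp_mode: str = "wrist",
    reference_noise: bool = True,
) -> CohortData:
    """Preprocess a cohort and build lagged designs with reference targets."""
    out = CohortData()
    for p in cohort:
        try:
            binned, report = preprocess_participant(p, config, temp_mode)
        except ExclusionError as err:
            logger.warning("participant %s excluded: %s", p.id, err.report.reasons)
            out.excluded[p.id] = err.report
            continue
        centers = binned.bin_centers
        rng = substream(config.rng_seed, f"reference/{p.id}") if reference_noise else None
        ref = reference_for_participant(p, source, (centers[0], centers[-1]), config, rng)
        design = build_lagged_design(binned, ref, config, participant_id=p.id,
                                     inlab_intervals=p.inlab)
        out.designs.append(design)
        out.measured[p.id] = ref.measured_phase
        out.reports[p.id] = report
    return out


@dataclass
class EvaluationResult:
    predicted: dict  # pid -> PhaseEstimate
    errors: dict  # pid -> signed minutes
    summary: ErrorSummary


def _score(predicted: dict, measured: dict) -> EvaluationResult:
    pids = [pid for pid in predicted if pid in measured]
    errors = {pid: phase_error(measured[pid], predicted[pid]) for pid in pids}
    summary = summarize(
        [errors[pid] for pid in pids],
        measured=[measured[pid].clock_time for pid in pids] if len(pids) >= 3 else None,
        predicted=[predicted[pid].clock_time for pid in pids] if len(pids) >= 3 else None,
    )
    return EvaluationResult(predicted, errors, summary)


def evaluate_loocv(data: CohortData, config: RunConfig,
                   source: str = "aMT6s") -> EvaluationResult:
    """Leave-one-out cross-validated phase predictions for a cohort."""
    folds = loocv(data.designs, config, rng=substream(config.rng_seed, "loocv"))
    predicted = {}
    for fold in folds:
        predicted[fold.participant_id] = predicted_phase(fold.times, fold.predicted,
                                                         source)
    return _score(predicted, data.measured)


def apply_model(model: TrainedModel, data: CohortData,
                source: str = "aMT6s") -> EvaluationResult:
    """Apply a final trained model to an independent cohort's designs."""
    predicted = {}
    for design in data.designs:
        rows = ~design.in_lab_mask
        if not rows.any():
            logger.warning("participant %s has no out-of-lab rows; skipped",
                           design.participant_id)
            continue
        pred = model.predict_design(design)
        predicted[design.participant_id] = predicted_phase(
            design.times[rows], pred[rows], source)
    return _score(predicted, data.measured)


def train_cohort_final(data: CohortData, config: RunConfig) -> TrainedModel:
    return train_final(data.designs, config,
                       rng=substream(config.rng_seed, "final"))
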