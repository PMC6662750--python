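"""Reading and writing the delimited text formats the pipeline touches.

On disk all tables are UTF-8 CSV. Timestamps are ISO-8601 civil local time
with no DST transitions; internally they become float minutes measured from
``EPOCH`` (midnight of recording day 0). A cohort is a directory with one
subdirectory per participant::

    cohort/
      P001/
        actigraphy.csv    timestamp,blue,white_lux,activity,off_wrist
        temperature.csv   timestamp,value,site,side
        sleep.csv         onset,offset,in_lab
        urine.csv         start,end,volume,concentration
        melatonin.csv     timestamp,value            (optional)
        inlab.csv         start,end                  (optional)
        removal_log.csv   start,end                  (optional)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    Participant,
    PhaseEstimate,
    SchemaError,
    SleepInterval,
    TEMPERATURE_SITES,
    UrineBlock,
)

logger = logging.getLogger("circaphase")

#: reference midnight for the minute <-> ISO conversion
EPOCH = pd.Timestamp("2024-01-01T00:00:00")

_SIDES = ("left", "right", "none")


class ParseError(ValueError):
    """A value in an input table could not be parsed."""


def minutes_to_iso(minutes: float | np.ndarray):
    ts = EPOCH + pd.to_timedelta(np.asarray(minutes, dtype=float), unit="m")
    if np.ndim(minutes) == 0:
        return pd.Timestamp(ts).isoformat()
    return pd.DatetimeIndex(ts).strftime("%Y-%m-%dT%H:%M:%S")


def iso_to_minutes(values: Iterable[str], context: str = "timestamp") -> np.ndarray:
    parsed = pd.to_datetime(list(values), errors="coerce", format="ISO8601")
    bad = np.flatnonzero(pd.isna(parsed))
    if bad.size:
        raise ParseError(f"malformed {context} at row {bad[0]}: {list(values)[bad[0]]!r}")
    return ((parsed - EPOCH) / pd.Timedelta(minutes=1)).to_numpy(dtype=float)


def _read_timestamped(path: Path, time_cols: tuple[str, ...]) -> pd.DataFrame:
    # round_trip parsing keeps write->read bit-exact for float columns
    df = pd.read_csv(path, float_precision="round_trip")
    for col in time_cols:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
        df[col] = iso_to_minutes(df[col].astype(str), context=f"{path.name}:{col}")
    return df


def _dedupe_sorted(df: pd.DataFrame, key: str, name: str) -> pd.DataFrame:
    df = df.sort_values(key, kind="stable")
    dup = df.duplicated(subset=[key], keep="last")
    if dup.any():
        logger.warning("%s: %d duplicate timestamps, keeping last record", name, int(dup.sum()))
        df = df[~dup]
    return df.reset_index(drop=True)


def read_participant(path: Path, schedule: str = "FS") -> Participant:
    path = Path(path)
    act = _read_timestamped(path / "actigraphy.csv", ("timestamp",))
    act = _dedupe_sorted(act, "timestamp", f"{path.name}/actigraphy")
    act["off_wrist"] = act["off_wrist"].astype(bool)

    temp = _read_timestamped(path / "temperature.csv", ("timestamp",))
    bad_site = set(temp["site"].unique()) - set(TEMPERATURE_SITES)
    if bad_site:
        raise SchemaError(f"{path.name}: unknown site label(s) {sorted(bad_site)}")
    bad_side = set(temp["side"].unique()) - set(_SIDES)
    if bad_side:
        raise SchemaError(f"{path.name}: unknown side label(s) {sorted(bad_side)}")
    temp = (
        temp.sort_values(["site", "side", "timestamp"], kind="stable")
        .drop_duplicates(subset=["site", "side", "timestamp"], keep="last")
        .reset_index(drop=True)
    )

    sleep = []
    sleep_path = path / "sleep.csv"
    if sleep_path.exists():
        sdf = _read_timestamped(sleep_path, ("onset", "offset"))
        for row in sdf.itertuples(index=False):
            sleep.append(SleepInterval(row.onset, row.offset, bool(row.in_lab)))

    urine = []
    urine_path = path / "urine.csv"
    if urine_path.exists():
        udf = _read_timestamped(urine_path, ("start", "end"))
        for row in udf.itertuples(index=False):
            urine.append(UrineBlock(row.start, row.end, float(row.volume), float(row.concentration)))

    melatonin = None
    mel_path = path / "melatonin.csv"
    if mel_path.exists():
        melatonin = _read_timestamped(mel_path, ("timestamp",))
        melatonin = _dedupe_sorted(melatonin, "timestamp", f"{path.name}/melatonin")

    inlab = []
    inlab_path = path / "inlab.csv"
    if inlab_path.exists():
        idf = _read_timestamped(inlab_path, ("start", "end"))
        inlab = [(row.start, row.end) for row in idf.itertuples(index=False)]

    removal = []
    rm_path = path / "removal_log.csv"
    if rm_path.exists():
        rdf = _read_timestamped(rm_path, ("start", "end"))
        removal = [(row.start, row.end) for row in rdf.itertuples(index=False)]

    return Participant(
        id=path.name,
        actigraphy=act,
        temperature=temp,
        sleep=sleep,
        urine=urine,
        melatonin=melatonin,
        inlab=inlab,
        temp_removal_log=removal,
        schedule=schedule,
    )


def read_cohort(root: str | Path, schedule: str = "FS") -> list[Participant]:
    """Load every participant subdirectory of ``root``, sorted by id.

    Missing values stay flagged (NaN), never dropped; rows are sorted and
    de-duplicated on timestamp (last record wins, with a warning).
    """
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if p.is_dir() and (p / "actigraphy.csv").exists())
    if not dirs:
        raise FileNotFoundError(f"no participant directories under {root}")
    return [read_participant(d, schedule=schedule) for d in dirs]


def _intervals_csv(intervals, names=("start", "end")) -> pd.DataFrame:
    return pd.DataFrame(
        {names[0]: [minutes_to_iso(a) for a, _ in intervals],
         names[1]: [minutes_to_iso(b) for _, b in intervals]}
    )


def write_participant(p: Participant, path: Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    act = p.actigraphy.copy()
    act["timestamp"] = minutes_to_iso(act["timestamp"].to_numpy())
    act.to_csv(path / "actigraphy.csv", index=False)

    temp = p.temperature.copy()
    temp["timestamp"] = minutes_to_iso(temp["timestamp"].to_numpy())
    temp.to_csv(path / "temperature.csv", index=False)

    pd.DataFrame(
        {
            "onset": [minutes_to_iso(s.onset) for s in p.sleep],
            "offset": [minutes_to_iso(s.offset) for s in p.sleep],
            "in_lab": [s.in_lab for s in p.sleep],
        }
    ).to_csv(path / "sleep.csv", index=False)

    pd.DataFrame(
        {
            "start": [minutes_to_iso(u.start) for u in p.urine],
            "end": [minutes_to_iso(u.end) for u in p.urine],
            "volume": [u.volume for u in p.urine],
            "concentration": [u.concentration for u in p.urine],
        }
    ).to_csv(path / "urine.csv", index=False)

    if p.melatonin is not None:
        mel = p.melatonin.copy()
        mel["timestamp"] = minutes_to_iso(mel["timestamp"].to_numpy())
        mel.to_csv(path / "melatonin.csv", index=False)
    if p.inlab:
        _intervals_csv(p.inlab).to_csv(path / "inlab.csv", index=False)
    if p.temp_removal_log:
        _intervals_csv(p.temp_removal_log).to_csv(path / "removal_log.csv", index=False)


def write_cohort(cohort: Iterable[Participant], root: str | Path) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        write_participant(p, root / p.id)


SUMMARY_COLUMNS = [
    "n", "mean", "median", "SD", "MAE", "medianAE", "SD_AE", "min_AE", "max_AE",
    "RMSE", "r", "p", "pct_within_15", "pct_within_30", "pct_within_60", "pct_within_120",
]


def write_results(
    estimates: Mapping[str, PhaseEstimate] | Iterable[tuple[str, PhaseEstimate]],
    summaries: Mapping[str, Mapping[str, float]],
    outdir: str | Path,
) -> None:
    """Write per-participant phase estimates and a summary-statistics table.

    ``estimates`` maps participant id -> PhaseEstimate; ``summaries`` maps a
    row label (model name) -> column dict with :data:`SUMMARY_COLUMNS` keys.
    Output is deterministic: the same inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = list(estimates.items()) if isinstance(estimates, Mapping) else list(estimates)
    if not items:
        logger.warning("write_results: empty estimate set, writing header-only tables")
    rows = [
        {
            "participant": pid,
            "method": est.method,
            "marker": est.marker,
            "clock_time_min": est.clock_time,
            "clock_hours": est.clock_hours,
            "flags": ";".join(est.flags),
        }
        for pid, est in sorted(items)
    ]
    pd.DataFrame(rows, columns=["participant", "method", "marker", "clock_time_min",
                                "clock_hours", "flags"]).to_csv(outdir / "phases.csv", index=False)

    srows = []
    for label in sorted(summaries):
        row = {"model": label}
        row.update({c: summaries[label].get(c, np.nan) for c in SUMMARY_COLUMNS})
        srows.append(row)
    pd.DataFrame(srows, columns=["model"] + SUMMARY_COLUMNS).to_csv(
        outdir / "summary.csv", index=False
    )
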