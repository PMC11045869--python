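"""CSV formats for minute records, criterion METs, participants and raw streams.

All files are plain UTF-8 comma-separated text with a header row; readers
validate column presence and vocabulary and report malformed rows with line
numbers, writers produce lossless round-trips.  Timestamps are serialized as
ISO-8601 at minute resolution (a strict-dialect flag accepts the watch's
``year/month/day hh:mm:ss`` display form on input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from datetime import datetime
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_trials import ParticipantProfile

WEAR_VOCABULARY = ("worn", "not_worn")

MINUTE_RECORD_COLUMNS = [
    "participant_id",
    "timestamp",
    "pa_avg",
    "pa_var",
    "steps",
    "lux1",
    "lux2",
    "lux3",
    "uv1",
    "uv2",
    "uv3",
    "wear_status",
]

RAW_STREAM_COLUMNS = ["participant_id", "timestamp", "ax", "ay", "az"]


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect or schema."""


class IntegrityError(ValueError):
    """Structurally valid data that violates a dataset-level invariant."""


@dataclass(frozen=True)
class MinuteRecord:
    """One smartwatch output row: the per-minute feature triple plus the
    light-sensor fields (three luminance and three UV readings per minute,
    carried through but unused by the MET model) and wear status."""

    participant_id: str
    timestamp: datetime
    pa_avg: float
    pa_var: float
    steps: int
    lux1: float
    lux2: float
    lux3: float
    uv1: float
    uv2: float
    uv3: float
    wear_status: str

    def __post_init__(self) -> None:
        if self.wear_status not in WEAR_VOCABULARY:
            raise FormatError(
                f"wear_status must be one of {WEAR_VOCABULARY}, "
                f"got {self.wear_status!r}"
            )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_timestamp(value: str, line: int, strict_watch_dialect: bool) -> datetime:
    text = str(value).strip()
    if strict_watch_dialect:
        for fmt in ("%Y/%m/%d %H:%M:%S", "%Y/%m/%d/%H:%M:%S"):
            try:
                return datetime.strptime(text, fmt)
            except ValueError:
                continue
    try:
        return datetime.fromisoformat(text)
    except ValueError as exc:
        raise FormatError(f"line {line}: unparseable timestamp {text!r}") from exc


def write_minute_records(records: Iterable[MinuteRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {f.name: getattr(rec, f.name) for f in fields(MinuteRecord)}
        row["timestamp"] = rec.timestamp.isoformat()
        rows.append(row)
    pd.DataFrame(rows, columns=MINUTE_RECORD_COLUMNS).to_csv(path, index=False)


def read_minute_records(
    path: str | Path, strict_watch_dialect: bool = False
) -> list[MinuteRecord]:
    """Parse a minute-record CSV; timestamps are truncated to minute resolution.

    Raises :class:`FormatError` naming the column or line for malformed input
    and :class:`IntegrityError` on duplicate participant-minutes.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(df, MINUTE_RECORD_COLUMNS, path)
    records: list[MinuteRecord] = []
    seen: set[tuple[str, datetime]] = set()
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        ts = _parse_timestamp(row["timestamp"], line, strict_watch_dialect)
        ts = ts.replace(second=0, microsecond=0)
        status = str(row["wear_status"]).strip()
        if status not in WEAR_VOCABULARY:
            raise FormatError(
                f"{path}: line {line}: wear_status {status!r} not in "
                f"{WEAR_VOCABULARY}"
            )
        key = (str(row["participant_id"]), ts)
        if key in seen:
            raise IntegrityError(
                f"{path}: line {line}: duplicate participant-minute {key}"
            )
        seen.add(key)
        records.append(
            MinuteRecord(
                participant_id=str(row["participant_id"]),
                timestamp=ts,
                pa_avg=float(row["pa_avg"]),
                pa_var=float(row["pa_var"]),
                steps=int(row["steps"]),
                lux1=float(row["lux1"]),
                lux2=float(row["lux2"]),
                lux3=float(row["lux3"]),
                uv1=float(row["uv1"]),
                uv2=float(row["uv2"]),
                uv3=float(row["uv3"]),
                wear_status=status,
            )
        )
    return records


def write_criterion_mets(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=["participant_id", "timestamp", "met"])


def read_criterion_mets(path: str | Path) -> pd.DataFrame:
    """Per-minute criterion (indirect-calorimetry) MET table.

    Columns ``participant_id, timestamp, met``; nonpositive METs are a hard
    error because a MET is a positive multiple of resting metabolism.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(df, ["participant_id", "timestamp", "met"], path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601").dt.floor("min")
    df["met"] = df["met"].astype(float)
    if (df["met"] <= 0).any():
        bad = int(df.index[df["met"] <= 0][0]) + 2
        raise FormatError(f"{path}: line {bad}: nonpositive criterion MET")
    return df


def write_participants(profiles: Iterable["ParticipantProfile"], path: str | Path) -> None:
    rows = [
        {
            "participant_id": p.id,
            "group": p.group,
            "gender": p.gender,
            "age": p.age,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_participants(path: str | Path, logger=None) -> list["ParticipantProfile"]:
    """Participant table; BMI is recomputed from height/weight on load.

    A BMI outside 10–60 kg·m⁻² is logged as a warning (likely a unit error)
    but the row is kept.
    """
    import logging

    from .synthetic_trials import ParticipantProfile

    log = logger or logging.getLogger(__name__)
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(
        df, ["participant_id", "group", "gender", "age", "height_cm", "weight_kg"], path
    )
    profiles = []
    for i, row in df.iterrows():
        p = ParticipantProfile(
            id=str(row["participant_id"]),
            group=str(row["group"]),
            gender=str(row["gender"]),
            age=float(row["age"]),
            height_cm=float(row["height_cm"]),
            weight_kg=float(row["weight_kg"]),
        )
        if not (10.0 <= p.bmi <= 60.0):
            log.warning(
                "%s: line %d: BMI %.1f outside plausible range 10-60",
                path,
                int(i) + 2,
                p.bmi,
            )
        profiles.append(p)
    return profiles


def write_raw_stream(
    windows: Iterable[tuple[str, "object"]], path: str | Path
) -> None:
    """Serialize (participant_id, MinuteWindow) pairs as a raw-stream CSV
    with one row per 0.5 s sample."""
    rows = []
    for pid, window in windows:
        start = window.minute_start or datetime(2000, 1, 1)
        for k in range(window.t.size):
            ts = start + pd.Timedelta(seconds=float(window.t[k]))
            rows.append(
                {
                    "participant_id": pid,
                    "timestamp": ts.isoformat(),
                    "ax": window.x[k],
                    "ay": window.y[k],
                    "az": window.z[k],
                }
            )
    pd.DataFrame(rows, columns=RAW_STREAM_COLUMNS).to_csv(path, index=False)


def read_raw_stream(path: str | Path) -> list[tuple[str, "object"]]:
    """Parse a raw-stream CSV back into per-minute windows.

    Samples are grouped by (participant, wall-clock minute); only complete
    120-sample minutes are returned, in time order.
    """
    from .signal_features import SAMPLES_PER_MINUTE, MinuteWindow

    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(df, RAW_STREAM_COLUMNS, path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["minute"] = df["timestamp"].dt.floor("min")
    out = []
    for (pid, minute), grp in df.groupby(["participant_id", "minute"], sort=True):
        if len(grp) != SAMPLES_PER_MINUTE:
            continue
        grp = grp.sort_values("timestamp")
        t = (grp["timestamp"] - minute).dt.total_seconds().to_numpy()
        out.append(
            (
                str(pid),
                MinuteWindow(
                    t=t,
                    x=grp["ax"].to_numpy(float),
                    y=grp["ay"].to_numpy(float),
                    z=grp["az"].to_numpy(float),
                    minute_start=minute.to_pydatetime(),
                ),
            )
        )
    return out
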