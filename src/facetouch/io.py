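"""File formats: sensor-stream CSV, calibration JSON, and the event log.

Stream CSV header: ``t,ax,ay,az,mx,my,mz`` — time in seconds (float),
acceleration in m/s^2, magnetic field in microtesla.  The magnetometer
columns are optional; without them only the inertial detector applies.

The event log is a plain text file, one detected event per line:
``start_iso,end_iso,kind,duration_s`` where ``kind`` is TA or HC and
``duration_s`` is the recorded duration (excess over 1 s for an HC).
Stream seconds are anchored to an origin timestamp (Unix epoch by default)
to produce ISO-8601 stamps.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

from .evalstats import AlertEvent, TouchEvent, classify_touch
from .exceptions import InvalidInputError
from .imudetect import ImuCalibration
from .magdetect import MagCalibration

__all__ = [
    "SensorSample",
    "read_stream",
    "write_stream",
    "write_labels",
    "save_calibration",
    "load_calibration",
    "write_event_log",
    "read_event_log",
]

STREAM_COLUMNS = ("t", "ax", "ay", "az", "mx", "my", "mz")
ACCEL_COLUMNS = ("t", "ax", "ay", "az")
EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


class SensorSample(NamedTuple):
    """One time-stamped reading: acceleration (m/s^2) and, when a
    magnetometer is present, magnetic field (uT)."""

    t: float
    ax: float
    ay: float
    az: float
    mx: float | None = None
    my: float | None = None
    mz: float | None = None


def read_stream(path: str | Path) -> pd.DataFrame:
    """Load a stream CSV; validates columns and sorted time.  Magnetometer
    columns may be absent."""
    frame = pd.read_csv(path)
    missing = [c for c in ACCEL_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"stream {path} lacks required columns {missing}")
    if frame["t"].is_monotonic_increasing is False:
        raise InvalidInputError(f"stream {path} has unsorted timestamps")
    return frame


def write_stream(frame: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in STREAM_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels[["t", "label", "script_id"]].to_csv(path, index=False)


def save_calibration(calibration, path: str | Path, timestamp: datetime | None = None) -> None:
    """Serialize a MagCalibration or ImuCalibration to JSON."""
    record = asdict(calibration)
    record["algo"] = "mag" if isinstance(calibration, MagCalibration) else "imu"
    record["timestamp"] = (timestamp or datetime.now(timezone.utc)).isoformat()
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def load_calibration(path: str | Path) -> MagCalibration | ImuCalibration:
    record = json.loads(Path(path).read_text())
    algo = record.pop("algo", None)
    record.pop("timestamp", None)
    if algo == "mag":
        return MagCalibration(**record)
    if algo == "imu":
        return ImuCalibration(**record)
    raise InvalidInputError(f"calibration file {path} lacks a valid 'algo' field")


def write_event_log(
    events: Sequence[AlertEvent | TouchEvent],
    path: str | Path,
    origin: datetime = EPOCH,
) -> None:
    """Write classified events as ``start_iso,end_iso,kind,duration_s``
    lines.  Raw :class:`AlertEvent`\\ s are classified on the fly."""
    lines = []
    for event in events:
        touch = event if isinstance(event, TouchEvent) else classify_touch(event)
        start = origin + timedelta(seconds=touch.event.start_s)
        end = origin + timedelta(seconds=touch.event.end_s)
        lines.append(f"{start.isoformat()},{end.isoformat()},{touch.kind},{touch.recorded_duration_s:.3f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_event_log(path: str | Path, origin: datetime = EPOCH) -> list[TouchEvent]:
    """Parse an event log back into classified events (stream seconds
    relative to ``origin``)."""
    events: list[TouchEvent] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        start_iso, end_iso, kind, duration = line.split(",")
        start = (datetime.fromisoformat(start_iso) - origin).total_seconds()
        end = (datetime.fromisoformat(end_iso) - origin).total_seconds()
        if kind not in ("TA", "HC"):
            raise InvalidInputError(f"unknown event kind {kind!r} in {path}")
        events.append(TouchEvent(kind, float(duration), AlertEvent(start, end)))
    return events
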