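"""Validated measurement capture and CSV round-trip.

Each entry is validated against its measure's input type before storage:

* keyboard — any finite number (the unit is a label only);
* list     — the raw value must be exactly one of the configured items;
* scale    — a number within the configured [min, max] range.

Accepted entries become :class:`Observation` records stamped with the
1-based trial day index and the phase label in force on that day, which is
what the summaries aggregate over.  Multiple observations of one measure on
the same day are all retained.
"""

from __future__ import annotations

import bisect
import csv
import io
import math
from datetime import date, datetime
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from .errors import CsvImportError, RecordingError
from .scheduling import phase_label_on_day, total_duration
from .trial_model import InputType, Measure, TrialSpec, require_valid

__all__ = [
    "Observation",
    "ObservationLog",
    "record",
    "export_csv",
    "import_csv",
]

CSV_COLUMNS = ("measure_id", "timestamp", "day_index", "phase_label", "value")


class Observation(BaseModel):
    """One validated measurement, stamped with trial day and phase."""

    model_config = ConfigDict(extra="forbid")

    measure_id: str
    timestamp: datetime
    day_index: int
    phase_label: str
    value: Union[float, str]


class ObservationLog(BaseModel):
    """Chronologically ordered, append-only collection of observations."""

    model_config = ConfigDict(extra="forbid")

    observations: list[Observation] = Field(default_factory=list)

    def append(self, obs: Observation) -> None:
        # insertion keeps chronological order even for out-of-order entry
        keys = [o.timestamp for o in self.observations]
        self.observations.insert(bisect.bisect_right(keys, obs.timestamp), obs)

    def for_measure(self, measure_id: str) -> list[Observation]:
        return [o for o in self.observations if o.measure_id == measure_id]

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)


def _parse_number(raw: Union[str, float, int]) -> float:
    if isinstance(raw, bool):
        raise RecordingError(f"not a number: {raw!r}", code="unparsable_number")
    if isinstance(raw, (int, float)):
        value = float(raw)
    else:
        try:
            value = float(str(raw).strip())
        except ValueError:
            raise RecordingError(f"not a number: {raw!r}",
                                 code="unparsable_number") from None
    if not math.isfinite(value):
        raise RecordingError(f"number must be finite, got {value}",
                             code="unparsable_number")
    return value


def _validate_value(measure: Measure, raw: Union[str, float, int]) -> Union[float, str]:
    if measure.input_type is InputType.KEYBOARD:
        return _parse_number(raw)
    if measure.input_type is InputType.SCALE:
        value = _parse_number(raw)
        sc = measure.scale_config
        if not sc.min <= value <= sc.max:
            raise RecordingError(
                f"value {value} outside scale range [{sc.min}, {sc.max}]",
                code="scale_out_of_range")
        return value
    items = measure.list_config.items
    if str(raw) not in items:
        raise RecordingError(f"{raw!r} is not one of the configured items {items}",
                             code="invalid_item")
    return str(raw)


def record(spec: TrialSpec, measure_id: str, raw: Union[str, float, int],
           at: datetime, start_date: Optional[date] = None) -> Observation:
    """Validate one entry and stamp it with day index and phase label.

    ``start_date`` anchors trial day 1 (defaults to the trial's creation
    date).  Entries outside the trial window are rejected.
    """
    require_valid(spec)
    measure = spec.measure_by_id(measure_id)
    if measure is None:
        raise RecordingError(f"no measure with id {measure_id!r}",
                             code="unknown_measure")
    anchor = start_date or spec.created_at.date()
    day_index = (at.date() - anchor).days + 1
    total = total_duration(spec.schedule)
    if not 1 <= day_index <= total:
        raise RecordingError(
            f"timestamp {at.isoformat()} falls on trial day {day_index}, "
            f"outside 1..{total}", code="outside_trial")
    return Observation(
        measure_id=measure_id,
        timestamp=at,
        day_index=day_index,
        phase_label=phase_label_on_day(spec.schedule, day_index),
        value=_validate_value(measure, raw),
    )


def export_csv(log: ObservationLog) -> str:
    """Render the log as RFC-4180 CSV (header always present)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for o in log.observations:
        value = repr(o.value) if isinstance(o.value, float) else o.value
        writer.writerow([o.measure_id, o.timestamp.isoformat(), o.day_index,
                         o.phase_label, value])
    return buf.getvalue()


def import_csv(text: str, spec: TrialSpec,
               start_date: Optional[date] = None) -> ObservationLog:
    """Parse and re-validate an observation CSV against the trial.

    Every row is pushed through :func:`record`, so stored day indices and
    phase labels are recomputed and checked; malformed or inconsistent rows
    are collected and reported with their line numbers.
    """
    require_valid(spec)
    reader = csv.reader(io.StringIO(text))
    rows = list(reader)
    if not rows or tuple(rows[0]) != CSV_COLUMNS:
        raise CsvImportError(
            f"expected header {','.join(CSV_COLUMNS)}", row_errors=[(1, "bad header")])
    log = ObservationLog()
    errors: list[tuple[int, str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        try:
            if len(row) != len(CSV_COLUMNS):
                raise ValueError(f"expected {len(CSV_COLUMNS)} fields, got {len(row)}")
            measure_id, ts, day_index, phase_label, value = row
            obs = record(spec, measure_id, value, datetime.fromisoformat(ts),
                         start_date=start_date)
            if obs.day_index != int(day_index) or obs.phase_label != phase_label:
                raise ValueError(
                    f"stamp mismatch: row says day {day_index}/{phase_label}, "
                    f"schedule says day {obs.day_index}/{obs.phase_label}")
            log.append(obs)
        except (RecordingError, ValueError) as exc:
            errors.append((lineno, str(exc)))
    if errors:
        raise CsvImportError(f"{len(errors)} bad row(s)", row_errors=errors)
    return log
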