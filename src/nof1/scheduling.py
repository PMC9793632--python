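"""Balanced phase sequences and the day/date calendar they induce.

Phases come in pairs (AB or BA) so that the sequence always contains equally
many A and B phases — an unbalanced sequence such as AABB confounds the
phase contrast with temporal trends.  Two orderings are offered:

* ``alternating``      — AB repeated: ABAB, ABABAB, ...
* ``counterbalanced``  — pair orientation alternates: ABBA, ABBAAB, ...
  (pair k is AB for odd k, BA for even k).  For two pairs this is the
  classic ABBA motif; the blockwise extension to more pairs preserves both
  balance and the motif.

Day indexing is 1-based with inclusive spans.  Calendar dates are whole
local days; attaching them is optional.

The meaning of the labels depends on the design: in a withdrawal trial A is
the intervention phase and B the no-intervention phase; in an
alternating-treatment trial A carries the first-entered intervention and B
the second.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .trial_model import (
    Design,
    Intervention,
    PhaseOrder,
    Schedule,
    TrialSpec,
    require_valid,
)

__all__ = [
    "PhaseSpan",
    "PhaseSequence",
    "generate_phase_sequence",
    "phase_calendar",
    "total_duration",
    "phase_label_on_day",
    "phase_ordinal_on_day",
    "active_intervention_on_day",
]


class PhaseSpan(BaseModel):
    """One contiguous phase: label plus its inclusive day range."""

    model_config = ConfigDict(extra="forbid")

    label: str  # "A" or "B"
    ordinal: int  # 1-based position in the sequence
    start_day: int
    end_day: int
    start_date: Optional[date] = None
    end_date: Optional[date] = None

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1


class PhaseSequence(BaseModel):
    """The realized, ordered list of phase spans for one trial."""

    model_config = ConfigDict(extra="forbid")

    phases: list[PhaseSpan] = Field(default_factory=list)

    @property
    def total_days(self) -> int:
        return self.phases[-1].end_day if self.phases else 0

    def span_on_day(self, day: int) -> PhaseSpan:
        if not 1 <= day <= self.total_days:
            raise ValueError(f"day {day} outside trial range 1..{self.total_days}")
        for span in self.phases:
            if span.start_day <= day <= span.end_day:
                return span
        raise AssertionError("contiguous spans cover every day")  # pragma: no cover

    def label_on_day(self, day: int) -> str:
        return self.span_on_day(day).label

    def labels(self) -> list[str]:
        return [s.label for s in self.phases]


def generate_phase_sequence(n_phase_pairs: int, order: PhaseOrder | str) -> list[str]:
    """Return the label sequence for ``n_phase_pairs`` pairs under ``order``.

    Always 2p labels with exactly p of each; e.g. (2, alternating) -> ABAB,
    (2, counterbalanced) -> ABBA, (3, counterbalanced) -> ABBAAB.
    """
    if n_phase_pairs < 1:
        raise ValueError(f"n_phase_pairs must be >= 1, got {n_phase_pairs}")
    order = PhaseOrder(order)
    labels: list[str] = []
    for k in range(1, n_phase_pairs + 1):
        if order is PhaseOrder.ALTERNATING or k % 2 == 1:
            labels += ["A", "B"]
        else:
            labels += ["B", "A"]
    return labels


def total_duration(schedule: Schedule) -> int:
    """Trial length in days: 2 * n_phase_pairs * phase_duration_days."""
    return 2 * schedule.n_phase_pairs * schedule.phase_duration_days


def phase_calendar(schedule: Schedule, start_date: Optional[date] = None) -> PhaseSequence:
    """Expand a schedule into labeled day spans, optionally dated.

    Day 1 falls on ``start_date`` when given; spans are contiguous,
    non-overlapping, and each ``phase_duration_days`` long.
    """
    if schedule.phase_duration_days < 1 or schedule.n_phase_pairs < 1:
        raise ValueError("schedule requires phase_duration_days >= 1 and n_phase_pairs >= 1")
    d = schedule.phase_duration_days
    spans = []
    for i, label in enumerate(generate_phase_sequence(schedule.n_phase_pairs, schedule.order)):
        start_day = i * d + 1
        end_day = start_day + d - 1
        spans.append(PhaseSpan(
            label=label,
            ordinal=i + 1,
            start_day=start_day,
            end_day=end_day,
            start_date=start_date + timedelta(days=start_day - 1) if start_date else None,
            end_date=start_date + timedelta(days=end_day - 1) if start_date else None,
        ))
    return PhaseSequence(phases=spans)


def _check_day(schedule: Schedule, day: int) -> None:
    total = total_duration(schedule)
    if not 1 <= day <= total:
        raise ValueError(f"day {day} outside trial range 1..{total}")


def phase_label_on_day(schedule: Schedule, day: int) -> str:
    """Phase label ("A"/"B") in force on a 1-based trial day."""
    _check_day(schedule, day)
    labels = generate_phase_sequence(schedule.n_phase_pairs, schedule.order)
    return labels[(day - 1) // schedule.phase_duration_days]


def phase_ordinal_on_day(schedule: Schedule, day: int) -> int:
    """1-based ordinal of the phase containing a trial day."""
    _check_day(schedule, day)
    return (day - 1) // schedule.phase_duration_days + 1


def active_intervention_on_day(spec: TrialSpec, day: int) -> Optional[Intervention]:
    """Which intervention (if any) the participant performs on a trial day.

    Withdrawal design: the single intervention on A days, nothing on B days.
    Alternating-treatment design: intervention 1 on A days, intervention 2
    on B days.
    """
    require_valid(spec)
    label = phase_label_on_day(spec.schedule, day)
    if spec.design is Design.WITHDRAWAL:
        return spec.interventions[0] if label == "A" else None
    return spec.interventions[0] if label == "A" else spec.interventions[1]
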