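"""Expansion of reminder policies into a dated task calendar.

Each intervention and each measure carries its own reminder policy (one or
more times of day, recurring daily or every x days, anchored at trial
day 1).  The engine turns those policies into concrete to-dos:

* a *measurement* task per (measure, reminder time) on every covered day —
  measures are collected in all phases, since the results compare phases;
* an *intervention* task per (intervention, reminder time) on covered days
  on which that intervention is actually active.  In a withdrawal trial
  this suppresses intervention reminders during no-intervention (B) phases,
  so the participant is never prompted to perform the intervention in a
  phase that is meant to go without it.

A task not completed by the end of its calendar day counts as missed.
"""

from __future__ import annotations

from datetime import date, datetime
from enum import Enum
from typing import Iterable, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from .errors import TaskError
from .scheduling import active_intervention_on_day, phase_label_on_day, total_duration
from .trial_model import Recurrence, ReminderPolicy, TrialSpec, require_valid

__all__ = [
    "TaskKind",
    "TaskStatus",
    "Task",
    "TaskLog",
    "recurrence_days",
    "tasks_for_day",
    "notification_schedule",
    "mark_completed",
    "mark_missed",
    "adherence_rate",
]


class TaskKind(str, Enum):
    INTERVENTION = "intervention"
    MEASUREMENT = "measurement"


class TaskStatus(str, Enum):
    PENDING = "pending"
    COMPLETED = "completed"
    MISSED = "missed"


class Task(BaseModel):
    """One dated, timed to-do generated from a reminder."""

    model_config = ConfigDict(extra="forbid")

    date: date
    time: str  # HH:MM, the notification time
    kind: TaskKind
    component_id: str
    component_name: str
    day_index: int
    phase_label: str
    status: TaskStatus = TaskStatus.PENDING
    completed_at: Optional[datetime] = None

    @property
    def uid(self) -> str:
        """Stable identity within one trial's calendar."""
        return f"{self.day_index}/{self.time}/{self.kind.value}/{self.component_id}"

    @property
    def due_at(self) -> datetime:
        hh, mm = self.time.split(":")
        return datetime.combine(self.date, datetime.min.time()).replace(
            hour=int(hh), minute=int(mm))


class TaskLog(BaseModel):
    """All tasks of one trial with their completion state."""

    model_config = ConfigDict(extra="forbid")

    tasks: list[Task] = Field(default_factory=list)

    def find(self, ref: Union[Task, str]) -> Task:
        uid = ref.uid if isinstance(ref, Task) else ref
        for t in self.tasks:
            if t.uid == uid:
                return t
        raise TaskError(f"no such task: {uid}", code="unknown_task")

    def to_jsonl(self) -> str:
        """One task per line, ready for appending to a log file."""
        return "".join(t.model_dump_json(exclude_none=True) + "\n" for t in self.tasks)

    @classmethod
    def from_jsonl(cls, text: str) -> "TaskLog":
        tasks = [Task.model_validate_json(line) for line in text.splitlines() if line.strip()]
        return cls(tasks=tasks)


def recurrence_days(policy: ReminderPolicy, total_days: int) -> set[int]:
    """Day indices (1-based) on which a reminder policy fires.

    ``daily`` covers every day; ``every_x_days`` covers 1, 1+x, 1+2x, ...
    within the trial.
    """
    if total_days < 1:
        raise ValueError("total_days must be >= 1")
    if policy.recurrence is Recurrence.DAILY:
        return set(range(1, total_days + 1))
    x = policy.interval_days
    if x is None or x < 2:
        raise ValueError("every_x_days policy requires interval_days >= 2")
    return set(range(1, total_days + 1, x))


def _day_date(spec: TrialSpec, day: int, start_date: Optional[date]) -> date:
    from datetime import timedelta
    anchor = start_date or spec.created_at.date()
    return anchor + timedelta(days=day - 1)


def tasks_for_day(spec: TrialSpec, day: int,
                  start_date: Optional[date] = None) -> list[Task]:
    """All tasks due on one trial day, sorted by reminder time.

    ``start_date`` anchors day 1 on the calendar; it defaults to the trial's
    creation date.
    """
    require_valid(spec)
    total = total_duration(spec.schedule)
    if not 1 <= day <= total:
        raise ValueError(f"day {day} outside trial range 1..{total}")
    label = phase_label_on_day(spec.schedule, day)
    when = _day_date(spec, day, start_date)
    out: list[Task] = []

    active = active_intervention_on_day(spec, day)
    for iv in spec.interventions:
        if active is None or iv.id != active.id:
            continue
        if day not in recurrence_days(iv.reminder, total):
            continue
        for t in iv.reminder.times:
            out.append(Task(date=when, time=t, kind=TaskKind.INTERVENTION,
                            component_id=iv.id, component_name=iv.name,
                            day_index=day, phase_label=label))
    for m in spec.measures:
        if day not in recurrence_days(m.reminder, total):
            continue
        for t in m.reminder.times:
            out.append(Task(date=when, time=t, kind=TaskKind.MEASUREMENT,
                            component_id=m.id, component_name=m.name,
                            day_index=day, phase_label=label))

    out.sort(key=lambda t: (t.time, t.kind.value, t.component_name, t.component_id))
    return out


def notification_schedule(spec: TrialSpec,
                          start_date: Optional[date] = None) -> TaskLog:
    """The full pending task calendar for a trial, day by day."""
    require_valid(spec)
    tasks: list[Task] = []
    for day in range(1, total_duration(spec.schedule) + 1):
        tasks.extend(tasks_for_day(spec, day, start_date))
    return TaskLog(tasks=tasks)


def mark_completed(log: TaskLog, ref: Union[Task, str], at: datetime) -> TaskLog:
    """Mark a pending task completed at ``at``; transitions are one-way."""
    task = log.find(ref)
    if task.status is not TaskStatus.PENDING:
        raise TaskError(f"task {task.uid} is already {task.status.value}",
                        code="not_pending")
    task.status = TaskStatus.COMPLETED
    task.completed_at = at
    return log


def mark_missed(log: TaskLog, ref: Union[Task, str]) -> TaskLog:
    """Mark a pending task as missed (its day has ended without completion)."""
    task = log.find(ref)
    if task.status is not TaskStatus.PENDING:
        raise TaskError(f"task {task.uid} is already {task.status.value}",
                        code="not_pending")
    task.status = TaskStatus.MISSED
    return log


def sweep_missed(log: TaskLog, as_of: datetime) -> TaskLog:
    """Turn every pending task whose day ended before ``as_of`` into missed."""
    for t in log.tasks:
        if t.status is TaskStatus.PENDING and t.date < as_of.date():
            t.status = TaskStatus.MISSED
    return log


def adherence_rate(log: TaskLog, as_of: Optional[datetime] = None) -> float:
    """Fraction of due tasks completed: completed / (completed + missed + overdue).

    With ``as_of`` given, pending tasks whose calendar day has not yet ended
    are excluded from the denominator; without it the trial is treated as
    over and every task counts.
    """
    completed = missed = overdue = 0
    for t in log.tasks:
        if t.status is TaskStatus.COMPLETED:
            completed += 1
        elif t.status is TaskStatus.MISSED:
            missed += 1
        elif as_of is None or t.date < as_of.date():
            overdue += 1
    denom = completed + missed + overdue
    if denom == 0:
        raise TaskError("no tasks due yet; adherence undefined", code="no_due_tasks")
    return completed / denom
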