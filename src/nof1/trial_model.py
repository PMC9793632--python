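"""Trial specification: domain types, validation, canonical JSON.

An N-of-1 trial is defined by four user-configurable components — a goal,
one or two interventions, one or more measures, and a schedule.  Two designs
are supported: a *withdrawal* design evaluates a single intervention against
no-intervention phases, and an *alternating-treatment* design compares two
interventions phase by phase.

The document model is deliberately lenient at parse time (every component
may be absent) so that a partially filled trial can be represented and the
missing pieces reported by :func:`validate_trial` as data rather than as
exceptions — mirroring a step-by-step creation flow.  Operations whose
precondition is a *complete* trial raise :class:`~nof1.errors.InvalidTrialError`.
"""

from __future__ import annotations

import json
import re
import uuid
from datetime import datetime
from enum import Enum
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import InvalidTrialError, TrialParseError, TrialSchemaError

__all__ = [
    "Design",
    "InputType",
    "Recurrence",
    "PhaseOrder",
    "Goal",
    "ReminderPolicy",
    "Intervention",
    "KeyboardConfig",
    "ListConfig",
    "ScaleAnnotation",
    "ScaleConfig",
    "Measure",
    "Schedule",
    "TrialSpec",
    "Violation",
    "ValidationReport",
    "validate_trial",
    "default_schedule",
    "to_json",
    "from_json",
    "clone_trial",
    "new_id",
]

_TIME_RE = re.compile(r"^([01]\d|2[0-3]):[0-5]\d$")


def new_id() -> str:
    """Fresh opaque identifier (UUID4 hex)."""
    return uuid.uuid4().hex


class Design(str, Enum):
    WITHDRAWAL = "withdrawal"
    ALTERNATING_TREATMENT = "alternating_treatment"


class InputType(str, Enum):
    KEYBOARD = "keyboard"
    LIST = "list"
    SCALE = "scale"


class Recurrence(str, Enum):
    DAILY = "daily"
    EVERY_X_DAYS = "every_x_days"


class PhaseOrder(str, Enum):
    ALTERNATING = "alternating"
    COUNTERBALANCED = "counterbalanced"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Goal(_Model):
    """What the user wants to achieve; free text plus an optional rationale."""

    name: str = ""
    rationale: Optional[str] = None


class ReminderPolicy(_Model):
    """Times of day plus a recurrence rule that generate concrete tasks.

    ``times`` are local ``HH:MM`` strings, strictly increasing within the
    day.  ``interval_days`` (x >= 2) is present exactly when recurrence is
    ``every_x_days``; the cycle is anchored at trial day 1.
    """

    times: list[str] = Field(default_factory=list)
    recurrence: Recurrence = Recurrence.DAILY
    interval_days: Optional[int] = None


class Intervention(_Model):
    """A treatment or behaviour change under evaluation."""

    id: str = Field(default_factory=new_id)
    name: str = ""
    instructions: str = ""
    reminder: ReminderPolicy = Field(default_factory=ReminderPolicy)


class KeyboardConfig(_Model):
    """Free numeric entry; ``unit`` is a display label, not a dimension."""

    unit: str = ""


class ListConfig(_Model):
    """Categorical choice among at least two distinct items."""

    items: list[str] = Field(default_factory=list)


class ScaleAnnotation(_Model):
    position: float
    label: str


class ScaleConfig(_Model):
    """Bounded numeric scale; annotations are display metadata only."""

    min: float = 0.0
    max: float = 10.0
    annotations: list[ScaleAnnotation] = Field(default_factory=list)


class Measure(_Model):
    """A data item collected to evaluate the goal.

    Exactly the config matching ``input_type`` must be present: keyboard
    (free number with unit), list (categorical), or scale (bounded number).
    """

    id: str = Field(default_factory=new_id)
    name: str = ""
    input_type: InputType = InputType.KEYBOARD
    keyboard_config: Optional[KeyboardConfig] = None
    list_config: Optional[ListConfig] = None
    scale_config: Optional[ScaleConfig] = None
    reminder: ReminderPolicy = Field(default_factory=ReminderPolicy)

    def active_config(self):
        return {
            InputType.KEYBOARD: self.keyboard_config,
            InputType.LIST: self.list_config,
            InputType.SCALE: self.scale_config,
        }[self.input_type]


class Schedule(_Model):
    """Phase layout: duration d (days), number of phase pairs p, and order.

    A phase pair is an AB or BA block; pairing keeps the count of A and B
    phases equal.  ``alternating`` repeats AB (ABAB...); ``counterbalanced``
    alternates the pair orientation (ABBA...).
    """

    phase_duration_days: int = 7
    n_phase_pairs: int = 2
    order: PhaseOrder = PhaseOrder.ALTERNATING


def default_schedule() -> Schedule:
    """The schedule proposed for every new trial: 7-day phases, sequence ABAB.

    Two phase pairs of one week each give a 28-day trial; the user can edit
    any of the three knobs afterwards.
    """
    return Schedule(phase_duration_days=7, n_phase_pairs=2, order=PhaseOrder.ALTERNATING)


class TrialSpec(_Model):
    """The complete user-defined trial document.

    The four component categories — goal, interventions, measures, schedule —
    are the only top-level sections besides identity metadata.
    """

    id: str = Field(default_factory=new_id)
    created_at: datetime = Field(default_factory=lambda: datetime.now().replace(microsecond=0))
    goal: Optional[Goal] = None
    design: Optional[Design] = None
    interventions: list[Intervention] = Field(default_factory=list)
    measures: list[Measure] = Field(default_factory=list)
    schedule: Schedule = Field(default_factory=default_schedule)

    def measure_by_id(self, measure_id: str) -> Optional[Measure]:
        for m in self.measures:
            if m.id == measure_id:
                return m
        return None


# --------------------------------------------------------------------------
# Validation

class Violation(_Model):
    """One broken invariant: a machine-readable code plus the offending path."""

    code: str
    path: str
    message: str


class ValidationReport(_Model):
    violations: list[Violation] = Field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == valid, so `if report:` reads naturally
        return self.is_valid

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)

    def codes(self) -> list[str]:
        return [v.code for v in self.violations]


def _check_reminder(policy: ReminderPolicy, path: str, out: list[Violation]) -> None:
    if not policy.times:
        out.append(Violation(code="reminder_times_empty", path=f"{path}.times",
                             message="reminder needs at least one time of day"))
    bad_format = [t for t in policy.times if not _TIME_RE.match(t)]
    if bad_format:
        out.append(Violation(code="reminder_time_format", path=f"{path}.times",
                             message=f"times must be HH:MM, got {bad_format!r}"))
    elif policy.times != sorted(set(policy.times)):
        out.append(Violation(code="reminder_times_order", path=f"{path}.times",
                             message="times must be strictly increasing within the day"))
    if policy.recurrence is Recurrence.EVERY_X_DAYS:
        if policy.interval_days is None or policy.interval_days < 2:
            out.append(Violation(code="reminder_interval", path=f"{path}.interval_days",
                                 message="every_x_days requires an interval x >= 2"))
    elif policy.interval_days is not None:
        out.append(Violation(code="reminder_interval", path=f"{path}.interval_days",
                             message="interval_days is only meaningful with every_x_days"))


def _check_measure(measure: Measure, path: str, out: list[Violation]) -> None:
    if not measure.name.strip():
        out.append(Violation(code="name_empty", path=f"{path}.name",
                             message="measure name must be non-empty"))
    present = {
        InputType.KEYBOARD: measure.keyboard_config is not None,
        InputType.LIST: measure.list_config is not None,
        InputType.SCALE: measure.scale_config is not None,
    }
    if not present[measure.input_type] or sum(present.values()) != 1:
        out.append(Violation(
            code="measure_config_mismatch", path=path,
            message=f"exactly the {measure.input_type.value}_config must be present"))
    if measure.input_type is InputType.SCALE and measure.scale_config is not None:
        sc = measure.scale_config
        if not sc.min < sc.max:
            out.append(Violation(code="scale_range", path=f"{path}.scale_config",
                                 message=f"scale requires min < max, got [{sc.min}, {sc.max}]"))
        else:
            for i, ann in enumerate(sc.annotations):
                if not sc.min <= ann.position <= sc.max:
                    out.append(Violation(
                        code="scale_annotation_range",
                        path=f"{path}.scale_config.annotations.{i}",
                        message=f"annotation at {ann.position} outside [{sc.min}, {sc.max}]"))
    if measure.input_type is InputType.LIST and measure.list_config is not None:
        items = measure.list_config.items
        if len(set(items)) < 2 or len(items) != len(set(items)):
            out.append(Violation(code="list_items", path=f"{path}.list_config.items",
                                 message="list measures need >= 2 distinct items"))
    _check_reminder(measure.reminder, f"{path}.reminder", out)


_EXPECTED_COUNT = {Design.WITHDRAWAL: 1, Design.ALTERNATING_TREATMENT: 2}


def validate_trial(spec: TrialSpec) -> ValidationReport:
    """Check every domain invariant; violations are data, not exceptions.

    An empty report means the trial is complete and internally consistent.
    Each broken invariant appears once with a stable code and the dotted
    path of the offending field.
    """
    out: list[Violation] = []

    if not spec.id.strip():
        out.append(Violation(code="id_empty", path="id", message="trial id must be non-empty"))

    if spec.goal is None:
        out.append(Violation(code="goal_missing", path="goal", message="a goal is required"))
    elif not spec.goal.name.strip():
        out.append(Violation(code="name_empty", path="goal.name",
                             message="goal name must be non-empty"))

    if spec.design is None:
        out.append(Violation(code="design_missing", path="design",
                             message="a design (withdrawal or alternating_treatment) is required"))
    else:
        expected = _EXPECTED_COUNT[spec.design]
        if len(spec.interventions) != expected:
            out.append(Violation(
                code="design_intervention_mismatch", path="interventions",
                message=(f"{spec.design.value} design requires exactly {expected} "
                         f"intervention(s), got {len(spec.interventions)}")))

    for i, iv in enumerate(spec.interventions):
        if not iv.name.strip():
            out.append(Violation(code="name_empty", path=f"interventions.{i}.name",
                                 message="intervention name must be non-empty"))
        _check_reminder(iv.reminder, f"interventions.{i}.reminder", out)

    if not spec.measures:
        out.append(Violation(code="measures_empty", path="measures",
                             message="at least one measure is required"))
    for i, m in enumerate(spec.measures):
        _check_measure(m, f"measures.{i}", out)

    ids = [c.id for c in (*spec.interventions, *spec.measures)]
    if len(ids) != len(set(ids)):
        out.append(Violation(code="duplicate_component_id", path="interventions",
                             message="intervention/measure ids must be unique"))

    if spec.schedule.phase_duration_days < 1:
        out.append(Violation(code="phase_duration", path="schedule.phase_duration_days",
                             message="phase duration must be >= 1 day"))
    if spec.schedule.n_phase_pairs < 1:
        out.append(Violation(code="phase_pairs", path="schedule.n_phase_pairs",
                             message="number of phase pairs must be >= 1"))

    return ValidationReport(violations=out)


def require_valid(spec: TrialSpec) -> TrialSpec:
    """Raise :class:`InvalidTrialError` unless ``spec`` validates cleanly."""
    report = validate_trial(spec)
    if not report.is_valid:
        detail = "; ".join(f"{v.path}: {v.message}" for v in report)
        raise InvalidTrialError(f"invalid trial: {detail}", report=report)
    return spec


# --------------------------------------------------------------------------
# Canonical JSON serialization

_TOP_LEVEL_KEYS = ("created_at", "design", "goal", "id", "interventions",
                   "measures", "schedule")


def to_json(spec: TrialSpec, *, validate: bool = True) -> str:
    """Serialize to the canonical JSON dialect (UTF-8, sorted keys).

    By default the spec must be valid; pass ``validate=False`` to export a
    partially filled document (e.g. a draft).
    """
    if validate:
        require_valid(spec)
    payload = spec.model_dump(mode="json", exclude_none=True)
    return json.dumps(payload, sort_keys=True, ensure_ascii=False, indent=2)


def from_json(text: Union[str, bytes], *, partial: bool = False) -> TrialSpec:
    """Parse a trial document.

    Raises :class:`TrialParseError` for syntactically bad JSON and
    :class:`TrialSchemaError` (naming the offending paths) for JSON that is
    not a trial document.  With ``partial=True`` missing top-level components
    are tolerated so drafts can be loaded and then inspected with
    :func:`validate_trial`.
    """
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TrialParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise TrialSchemaError("trial document must be a JSON object", paths=["$"])
    if not partial:
        missing = [k for k in _TOP_LEVEL_KEYS if k not in data]
        if missing:
            raise TrialSchemaError(
                f"missing required key(s): {', '.join(missing)}", paths=missing)
    try:
        return TrialSpec.model_validate(data)
    except ValidationError as exc:
        paths = [".".join(str(p) for p in err["loc"]) for err in exc.errors()]
        raise TrialSchemaError(f"document does not match trial schema: {exc}",
                               paths=paths) from exc


def clone_trial(spec: TrialSpec) -> TrialSpec:
    """Deep copy with a fresh id and creation timestamp.

    Component ids are preserved so that libraries of observations remain
    interpretable against the source trial; everything is independently
    mutable.
    """
    require_valid(spec)
    return spec.model_copy(deep=True, update={
        "id": new_id(),
        "created_at": datetime.now().replace(microsecond=0),
    })
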