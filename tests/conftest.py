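"""Shared fixtures: hand-built trials and a random valid-trial generator."""

from __future__ import annotations

import random
from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from nof1 import (
    Design,
    Goal,
    InputType,
    Intervention,
    Measure,
    PhaseOrder,
    Recurrence,
    ReminderPolicy,
    Schedule,
    TrialSpec,
)

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

CREATED = datetime(2022, 1, 1, 12, 0, 0)


def make_withdrawal_trial(schedule: Schedule | None = None,
                          measure: Measure | None = None) -> TrialSpec:
    """Minimal valid withdrawal trial: one intervention, one scale measure."""
    return TrialSpec(
        id="trial-w",
        created_at=CREATED,
        goal=Goal(name="Reduce back pain"),
        design=Design.WITHDRAWAL,
        interventions=[Intervention(
            id="iv-1", name="Willow bark tea",
            instructions="Drink one cup in the morning.",
            reminder=ReminderPolicy(times=["08:00"]))],
        measures=[measure or Measure(
            id="m-pain", name="Pain level", input_type=InputType.SCALE,
            scale_config={"min": 0, "max": 10},
            reminder=ReminderPolicy(times=["21:00"]))],
        schedule=schedule or Schedule(),
    )


def make_alternating_trial(schedule: Schedule | None = None) -> TrialSpec:
    """Minimal valid alternating-treatment trial: two interventions."""
    return TrialSpec(
        id="trial-a",
        created_at=CREATED,
        goal=Goal(name="Treat leg cramps"),
        design=Design.ALTERNATING_TREATMENT,
        interventions=[
            Intervention(id="iv-1", name="Magnesium",
                         reminder=ReminderPolicy(times=["19:00"])),
            Intervention(id="iv-2", name="Massage",
                         reminder=ReminderPolicy(times=["21:00"])),
        ],
        measures=[Measure(
            id="m-cramps", name="Cramp intensity", input_type=InputType.KEYBOARD,
            keyboard_config={"unit": "0-10"},
            reminder=ReminderPolicy(times=["22:00"]))],
        schedule=schedule or Schedule(),
    )


@pytest.fixture
def withdrawal_trial() -> TrialSpec:
    return make_withdrawal_trial()


@pytest.fixture
def alternating_trial() -> TrialSpec:
    return make_alternating_trial()


def _random_reminder(rng: random.Random) -> ReminderPolicy:
    n_times = rng.randint(1, 3)
    times = sorted(rng.sample(
        [f"{h:02d}:{m:02d}" for h in range(6, 23) for m in (0, 30)], n_times))
    if rng.random() < 0.5:
        return ReminderPolicy(times=times)
    return ReminderPolicy(times=times, recurrence=Recurrence.EVERY_X_DAYS,
                          interval_days=rng.randint(2, 4))


def _random_measure(rng: random.Random, idx: int) -> Measure:
    kind = rng.choice(list(InputType))
    kwargs = {}
    if kind is InputType.KEYBOARD:
        kwargs["keyboard_config"] = {"unit": rng.choice(["hours", "kg", ""])}
    elif kind is InputType.LIST:
        items = rng.sample(["yes", "no", "maybe", "often", "rarely"],
                           rng.randint(2, 4))
        kwargs["list_config"] = {"items": items}
    else:
        lo = rng.randint(-5, 5)
        kwargs["scale_config"] = {"min": lo, "max": lo + rng.randint(1, 10)}
    return Measure(id=f"m-{idx}", name=f"measure {idx}", input_type=kind,
                   reminder=_random_reminder(rng), **kwargs)


def random_trial_spec(rng: random.Random) -> TrialSpec:
    """A random but always-valid trial, driven by a seeded ``random.Random``."""
    design = rng.choice(list(Design))
    n_iv = 1 if design is Design.WITHDRAWAL else 2
    interventions = [
        Intervention(id=f"iv-{i}", name=f"intervention {i}",
                     instructions="do the thing",
                     reminder=_random_reminder(rng))
        for i in range(n_iv)
    ]
    measures = [_random_measure(rng, i) for i in range(rng.randint(1, 3))]
    schedule = Schedule(phase_duration_days=rng.randint(1, 10),
                        n_phase_pairs=rng.randint(1, 5),
                        order=rng.choice(list(PhaseOrder)))
    return TrialSpec(
        id=f"trial-{rng.randrange(10**9)}",
        created_at=CREATED,
        goal=Goal(name="random goal",
                  rationale=rng.choice([None, "because"])),
        design=design,
        interventions=interventions,
        measures=measures,
        schedule=schedule,
    )
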