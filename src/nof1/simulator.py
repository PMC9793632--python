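"""Synthetic participant: outcome model plus imperfect adherence.

The generator walks the trial's full task calendar in order.  Each task is
completed with probability q (the adherence parameter); a completed
measurement task of a numeric measure produces an observation under a
linear outcome model

    y = mu + delta_active(day) + beta * day + eps,   eps ~ Normal(0, sigma^2)

where mu is the participant's baseline, delta_active is the effect of the
intervention active that day (0 on no-intervention days of a withdrawal
trial), beta is a per-day secular trend, and eps is independent Gaussian
noise — no autocorrelation or carryover in the base model, matching the
assumptions of the descriptive summaries downstream.  Scale-measure values
are clipped to the configured [min, max] *after* noise, mimicking a bounded
instrument.

Categorical (list) measures are skipped by default; with
``simulate_list_measures=True`` an item is drawn from an ordinal-shift
model: item k (0-based, K items) gets weight exp(eta * k / (K - 1)) with
eta = delta_active, so a positive effect shifts probability mass toward
later items and eta = 0 is uniform.

Everything is reproducible from the seed; a cohort derives per-participant
seeds from the master seed through numpy's splittable SeedSequence.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .recording import Observation, ObservationLog, record
from .scheduling import active_intervention_on_day
from .tasking import TaskKind, TaskLog, mark_completed, mark_missed, notification_schedule
from .trial_model import InputType, TrialSpec, require_valid

__all__ = ["SimulationConfig", "simulate_participant", "simulate_cohort"]


class SimulationConfig(BaseModel):
    """Outcome-model and adherence parameters of one synthetic participant.

    ``effects`` aligns with the trial's intervention list (missing entries
    count as 0); units are those of the simulated measure.
    """

    model_config = ConfigDict(extra="forbid")

    baseline: float = 5.0           # mu
    effects: list[float] = Field(default_factory=lambda: [1.0])  # delta per intervention
    trend: float = 0.0              # beta, per day
    noise_sd: float = 1.0           # sigma >= 0
    adherence: float = 0.9          # q, per-task completion probability
    seed: int = 0
    simulate_list_measures: bool = False

    def check(self) -> "SimulationConfig":
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must lie in [0, 1]")
        return self


def _effect_on_day(spec: TrialSpec, config: SimulationConfig, day: int) -> float:
    active = active_intervention_on_day(spec, day)
    if active is None:
        return 0.0
    idx = next(i for i, iv in enumerate(spec.interventions) if iv.id == active.id)
    return config.effects[idx] if idx < len(config.effects) else 0.0


def simulate_participant(spec: TrialSpec, config: SimulationConfig,
                         start_date: Optional[date] = None
                         ) -> tuple[TaskLog, ObservationLog]:
    """Run one synthetic participant through the trial's task calendar.

    Returns the task log (every task completed or missed) and the
    observation log of the recorded measurements.  Deterministic given
    (spec, config, start_date).
    """
    require_valid(spec)
    config.check()
    rng = np.random.default_rng(config.seed)
    task_log = notification_schedule(spec, start_date)
    obs_log = ObservationLog()

    for task in task_log.tasks:
        done = rng.random() < config.adherence
        if not done:
            mark_missed(task_log, task)
            continue
        mark_completed(task_log, task, at=task.due_at)
        if task.kind is not TaskKind.MEASUREMENT:
            continue
        measure = spec.measure_by_id(task.component_id)
        day = task.day_index
        delta = _effect_on_day(spec, config, day)
        if measure.input_type is InputType.LIST:
            if not config.simulate_list_measures:
                continue
            items = measure.list_config.items
            k = np.arange(len(items))
            denom = max(len(items) - 1, 1)
            weights = np.exp(delta * k / denom)
            value = items[int(rng.choice(len(items), p=weights / weights.sum()))]
        else:
            y = (config.baseline + delta + config.trend * day
                 + rng.normal(0.0, config.noise_sd))
            if measure.input_type is InputType.SCALE:
                sc = measure.scale_config
                y = min(max(y, sc.min), sc.max)
            value = y
        obs = record(spec, measure.id, value, at=task.due_at,
                     start_date=start_date)
        obs_log.append(obs)
    return task_log, obs_log


def simulate_cohort(spec: TrialSpec, config: SimulationConfig,
                    n_participants: int, seed: Optional[int] = None,
                    start_date: Optional[date] = None
                    ) -> list[tuple[TaskLog, ObservationLog]]:
    """Simulate n independent participants of one trial.

    Per-participant seeds are spawned from the master seed (``seed`` if
    given, else ``config.seed``) via ``numpy.random.SeedSequence``, so the
    cohort is reproducible as a whole and participant i is exactly
    :func:`simulate_participant` under their derived seed.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = config.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(n_participants)
    out = []
    for child in children:
        child_seed = int(child.generate_state(1)[0])
        participant_config = config.model_copy(update={"seed": child_seed})
        out.append(simulate_participant(spec, participant_config, start_date))
    return out
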