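# nof1 — an engine for self-directed N-of-1 trials

An N-of-1 trial is a multi-period crossover experiment in a single person:
conditions are applied in a predefined sequence of phases, an outcome is
measured throughout, and the phases are compared to learn what works *for
that individual*. This package is a headless engine for the user-centric
variant of such trials — the kind a person designs for themselves on a
phone — aimed at developers of self-experimentation tools and at
methodologists who want to study these designs computationally.

A trial is specified by four components:

- a **goal** (what the person wants to achieve),
- one or two **interventions** (a *withdrawal* design alternates one
  intervention with no-intervention phases; an *alternating-treatment*
  design compares two interventions),
- one or more **measures**, each with one of three input types — free
  numeric entry with a unit (*keyboard*), a categorical choice (*list*), or
  a bounded annotated *scale*,
- a **schedule**: phase duration *d*, number of phase pairs *p*, and a
  phase order. Phases are paired (AB or BA) so the sequence is always
  balanced; the order is either alternating (ABAB…) or counterbalanced
  (ABBA…). The default schedule is two pairs of 7-day phases, ABAB —
  28 days in total.

Around that specification the engine provides: validation with
machine-readable violation codes; a canonical JSON serialization with
round-trip identity; expansion of per-component reminder policies (times of
day, daily or every *x* days) into a dated task calendar with completion
tracking; validated measurement capture stamped with trial day and phase;
descriptive summaries by day and by phase; a phase contrast
mean(A) − mean(B) with an optional Welch two-sample *t*-test; a library of
preconfigured goal/intervention/measure templates with goal-linked
suggestions; and a synthetic-participant simulator (linear outcome model
with baseline μ, per-intervention effect δ, daily trend β, Gaussian noise
σ, and per-task adherence probability q) so the entire
create → run → summarize loop is testable without human participants.

## Worked example

```python
from datetime import datetime
from nof1 import *

trial = TrialSpec(
    id="back-pain-01",
    created_at=datetime(2022, 3, 1, 9, 0),
    goal=Goal(name="Reduce back pain"),
    design=Design.WITHDRAWAL,
    interventions=[Intervention(
        id="iv-tea", name="Willow bark tea",
        instructions="Drink one cup in the morning.",
        reminder=ReminderPolicy(times=["08:00"]))],
    measures=[Measure(
        id="m-pain", name="Pain level", input_type=InputType.SCALE,
        scale_config={"min": 0, "max": 10,
                      "annotations": [{"position": 0, "label": "no pain"},
                                      {"position": 10, "label": "worst pain"}]},
        reminder=ReminderPolicy(times=["21:00"]))],
)
print("valid:", validate_trial(trial).is_valid)
cal = phase_calendar(trial.schedule, trial.created_at.date())
print("phases:", [(s.label, s.start_day, s.end_day) for s in cal.phases])

config = SimulationConfig(baseline=6.0, effects=[-1.5], noise_sd=1.0,
                          adherence=0.9, seed=7)
tasks, observations = simulate_participant(trial, config)
print(f"tasks: {len(tasks.tasks)}, observations: {len(observations)}, "
      f"adherence: {adherence_rate(tasks):.3f}")
print(render_report(history_report(trial, observations)))
```

prints

```
valid: True
phases: [('A', 1, 7), ('B', 8, 14), ('A', 15, 21), ('B', 22, 28)]
tasks: 42, observations: 26, adherence: 0.952
Trial back-pain-01 (withdrawal)

Measure: Pain level [scale] — 26 observation(s)
  phase 1 (A): mean 4.047 over n=6
  phase 2 (B): mean 5.734 over n=7
  phase 3 (A): mean 3.793 over n=7
  phase 4 (B): mean 5.759 over n=6
  contrast A−B: -1.835 (mean A 3.910, n=13; mean B 5.746, n=13); Welch t=-7.953, df=23.9, p=0.0000
```

Reading the output: the default 28-day ABAB schedule generates 42 tasks
(one daily measurement reminder on all 28 days, one daily intervention
reminder on the 14 tea-drinking A-days). The simulated participant, whose
true tea effect is −1.5 pain points on a baseline of 6, completed 95% of
tasks and produced 26 pain ratings. Pooling all A-phase and all B-phase
ratings, the estimated phase contrast is −1.835 (true value −1.5, noise
σ = 1), and the Welch test finds the A/B difference clearly distinguishable
from zero for this person. Descriptive summaries like these are the
intended endpoint; the *t*-test is a convenience, not a substitute for a
model that accounts for trends or autocorrelation.

The same loop is available from the shell via the `nof1` command
(`validate`, `schedule`, `tasks`, `record`, `simulate`, `summarize`,
`library`, `export`; every subcommand takes `--format json`).

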