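# Methods

This note documents the design and modelling choices behind the engine: the
trial model and its invariants, the scheduling and tasking rules, the
summary statistics, the synthetic-participant model, and the places where
the design was genuinely open and a choice had to be made.

## Trial model

A trial is one goal, one or two interventions, at least one measure, and a
schedule. The coupling between design and intervention count is a hard
invariant: a withdrawal design has exactly one intervention (A = intervention,
B = no intervention), an alternating-treatment design exactly two
(A = intervention 1, B = intervention 2). Label A is always bound to the
first-entered intervention.

The document model is lenient at parse time — every component may be absent
— so a partially built trial can be represented and `validate_trial` can
report completeness section by section. Validation returns violations as
data (stable code + dotted path), never exceptions; operations that require
a complete trial call `require_valid` and raise with the full report
attached. Three failure layers are kept distinct on purpose: parse errors
(not JSON), schema errors (JSON but not a trial document; offending paths
named), and domain violations (a trial document breaking an invariant).

Canonical JSON uses sorted keys, UTF-8, and ISO-8601 timezone-naive local
timestamps; `from_json(to_json(s)) == s` holds exactly for every valid
trial, which the suite checks property-based. Interventions and measures
carry opaque ids (auto-generated UUID hex, caller-overridable) because
observations and tasks must reference components stably across renames.
`clone_trial` refreshes the trial id and creation timestamp but keeps
component ids, so old observation logs remain interpretable against the
clone's components.

## Phase sequences and the calendar

Phases come in pairs so the A/B counts are always equal; an unbalanced
sequence (e.g. AABB) confounds the phase contrast with any temporal trend.
Two orders are generated:

- **alternating** — AB repeated p times;
- **counterbalanced** — pair k is AB for odd k and BA for even k, giving
  ABBA for p = 2 and ABBAAB for p = 3.

The counterbalanced rule for p ≠ 2 is this package's own blockwise
extension of the ABBA motif; it preserves balance and reduces
position-in-trial confounding at every scale of two pairs. It is the one
scheduling rule with no external definition, hence stated prominently here
and pinned by tests.

Days are 1-based with inclusive spans; calendar dates are whole local days
(the data live on one device, so no cross-timezone semantics are defined).
Day 1 defaults to the trial's creation date wherever a date anchor is
needed; every such function takes an explicit `start_date` override. There
are no washout phases.

## Tasks and reminders

Reminder recurrence is anchored at trial day 1: `every_x_days` fires on
days 1, 1+x, 1+2x, … — the simplest consistent reading, deliberately *not*
re-anchored at phase boundaries. Measurement tasks are generated in every
phase regardless of design, because phase comparison requires data on both
sides. Intervention tasks are generated only on days the intervention is
active; in a withdrawal trial this suppresses intervention reminders during
B phases rather than prompting the user to break the no-intervention
condition. Task status transitions are one-way (pending → completed or
pending → missed); a task still pending after its calendar day has ended
counts as overdue and enters the adherence denominator:
adherence = completed / (completed + missed + overdue).

## Recording

Values are validated against the measure's input type before storage:
keyboard accepts any finite real (units are labels, not dimensioned
quantities — no conversion); list accepts exactly one of the configured
items; scale accepts reals in [min, max] inclusive (annotations are display
metadata; no step size is imposed, so the instrument is continuous).
Accepted values are stamped with day index and phase label derived from the
schedule — the stamp is always recomputed, never trusted from input, which
is also how CSV import re-validates every row and reports bad lines by line
number. Multiple observations of one measure on the same day are all kept;
reminder policies explicitly allow several times per day.

## Summaries

Aggregation is the arithmetic mean per day or per phase. The phase-level
mean pools all raw observations in the phase rather than averaging daily
means — the two differ when days have unequal numbers of entries, and
pooling weights each observation equally; the equality with a brute-force
pool is asserted in tests. Grains with no data are omitted, never imputed.
Categorical measures get per-item counts instead of means.

The phase contrast is mean(A) − mean(B) over all pooled A- and
B-observations (intervention minus control, or intervention 1 minus
intervention 2). The optional test is Welch's unequal-variance two-sample
t-test (scipy) — a robust default given no reason to assume equal phase
variances — with the Welch–Satterthwaite degrees of freedom. It is a single
test with no multiplicity correction and it ignores autocorrelation and
trends; it is offered as a descriptive convenience, which is also why the
report leads with the means.

## Synthetic participant

The simulator exists so the full loop runs and the summaries can be checked
for parameter recovery. For each task in calendar order the participant
completes it with probability q; a completed measurement of a numeric
measure yields

    y = mu + delta_active(day) + beta * day + eps,  eps ~ N(0, sigma^2)

with `delta_active` the effect of the day's active intervention (0 on
withdrawal B-days). Scale values are clipped to [min, max] *after* noise,
mimicking a bounded instrument — with means near a bound this biases
recovery, which is a property of bounded scales, not a bug. Defaults are
μ = 5, δ = (1,), β = 0, σ = 1, q = 0.9 on a 0–10 scale: a mid-scale
baseline, a one-point effect (one noise SD — detectable but not trivial in
28 days), no secular trend, and the high-but-imperfect adherence typical of
engaged self-trackers.

Noise is independent Gaussian per observation: no autocorrelation,
carryover, learning or behaviour change — exactly the assumptions of the
descriptive summaries, so passing recovery tests validates the pipeline,
not those assumptions against real behaviour. Categorical measures are
skipped by default; optionally an ordinal-shift variant draws item k
(0-based, K items) with weight exp(δ_active · k/(K−1)), uniform at zero
effect. Cohorts derive per-participant seeds from the master seed via
numpy's splittable `SeedSequence`, so a cohort is reproducible as a whole
and member i is exactly a single-participant run under its derived seed.

The suite's recovery checks use a 200-participant cohort of the default
28-day withdrawal trial under the default parameters (mean cohort contrast
within 3 empirical standard errors of δ; exact recovery in the noiseless
limit), and ≥ 500 tasks for the binomial adherence check — sizes at which
the checks are sharp while the whole suite stays in seconds.

## Component library

The shipped library links four goals to three suggested interventions each
(back pain → willow bark tea / arnica gel / warming pad; leg cramps →
magnesium / vitamin B12 / massage; rheumatoid arthritis → omega-3 / olive
oil massage / cold patch; irritable bowel syndrome → gluten-free /
fructose-free / low-fiber diet). Suggestions for a goal list its linked
interventions first, then the rest of the library. The non-linked goals,
interventions and measures are this package's own examples. Templates
carry complete default reminder policies (daily, one time of day) so every
template validates as soon as it is embedded in a trial; instantiation
deep-copies with a fresh id, leaving the library immutable in practice.
Content is a packaged JSON data file in the trial-component dialect, so the
library can be extended without code changes.

## Numerical and degenerate-input choices

- Scale bounds are inclusive; boundary values are valid entries.
- `NaN`/`inf` are rejected as unparsable wherever a number is expected.
- The phase contrast requires ≥ 1 observation per phase type (≥ 2 with the
  test); below that it raises `insufficient_data` rather than returning
  degenerate statistics. The history report degrades gracefully: test →
  means only → "no data".
- Adherence on a calendar with no due tasks is undefined and raises.
- Ties in task ordering within a day are broken by (time, kind, component
  name, component id) for determinism.
- Welch's t on two identical samples returns t = 0 (scipy emits a precision
  warning when variances are ~0; the value is still exact).

## Known limitations

No blinding or randomization (phase order is deterministic by design); no
washout modelling; no imputation of missing days; no autocorrelation-aware
inference or mixed models; no multi-arm designs beyond the two supported;
no power-based schedule recommendation. The simulator models outcome and
adherence, not behaviour change or learning effects.
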