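"""Descriptive results: per-day / per-phase aggregation and phase contrasts.

Numeric measures (keyboard, scale) are summarised by arithmetic means at
two grains — per trial day, or per phase (the phase mean pools all raw
observations falling in that phase, it is *not* a mean of daily means, so
days with more entries weigh more).  Days or phases without data are
omitted, never imputed.  Categorical (list) measures get per-item counts
instead of means.

The phase contrast compares all A-phase observations against all B-phase
observations, reported as mean_A − mean_B (intervention minus control in a
withdrawal trial, intervention 1 minus intervention 2 in an
alternating-treatment trial).  Optionally a Welch two-sample t-test (no
equal-variance assumption) is attached; a single test, no multiplicity
correction.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .errors import SummaryError
from .recording import ObservationLog
from .scheduling import phase_label_on_day, phase_ordinal_on_day
from .trial_model import InputType, Schedule, TrialSpec, require_valid

__all__ = [
    "AggregatedPoint",
    "AggregatedSeries",
    "FrequencyPoint",
    "PhaseContrast",
    "aggregate",
    "list_frequencies",
    "phase_contrast",
    "history_report",
    "render_report",
]


class AggregatedPoint(BaseModel):
    model_config = ConfigDict(extra="forbid")

    index: int  # day number, or phase ordinal
    phase_label: str
    n: int
    mean: float


class AggregatedSeries(BaseModel):
    model_config = ConfigDict(extra="forbid")

    measure_id: str
    grain: str  # "day" | "phase"
    points: list[AggregatedPoint] = Field(default_factory=list)


class FrequencyPoint(BaseModel):
    model_config = ConfigDict(extra="forbid")

    index: int
    phase_label: str
    counts: dict[str, int]


class PhaseContrast(BaseModel):
    """mean_A − mean_B with sample sizes and an optional Welch t-test."""

    model_config = ConfigDict(extra="forbid")

    measure_id: str
    mean_a: float
    mean_b: float
    difference: float
    n_a: int
    n_b: int
    t_statistic: Optional[float] = None
    df: Optional[float] = None
    p_value: Optional[float] = None


def _numeric_frame(log: ObservationLog, measure_id: str,
                   schedule: Optional[Schedule]) -> pd.DataFrame:
    rows = []
    for o in log.for_measure(measure_id):
        if not isinstance(o.value, (int, float)) or isinstance(o.value, bool):
            raise SummaryError(
                f"measure {measure_id!r} has categorical values; "
                "means are undefined — use list_frequencies",
                code="non_numeric_measure")
        rows.append({
            "day_index": o.day_index,
            "phase_label": o.phase_label,
            "phase_ordinal": (phase_ordinal_on_day(schedule, o.day_index)
                              if schedule is not None else None),
            "value": float(o.value),
        })
    return pd.DataFrame(rows, columns=["day_index", "phase_label",
                                       "phase_ordinal", "value"])


def aggregate(log: ObservationLog, measure_id: str, grain: str = "day",
              schedule: Optional[Schedule] = None) -> AggregatedSeries:
    """Mean of a numeric measure per day or per phase.

    Phase grain needs the trial ``schedule`` to map day indices onto phase
    ordinals.  Grains with no data are omitted.
    """
    if grain not in ("day", "phase"):
        raise ValueError(f"grain must be 'day' or 'phase', got {grain!r}")
    if grain == "phase" and schedule is None:
        raise ValueError("phase-grain aggregation requires the trial schedule")
    df = _numeric_frame(log, measure_id, schedule)
    if df.empty:
        return AggregatedSeries(measure_id=measure_id, grain=grain)
    key = "day_index" if grain == "day" else "phase_ordinal"
    grouped = df.groupby(key, sort=True).agg(
        n=("value", "size"), mean=("value", "mean"),
        phase_label=("phase_label", "first"))
    points = [AggregatedPoint(index=int(idx), phase_label=row["phase_label"],
                              n=int(row["n"]), mean=float(row["mean"]))
              for idx, row in grouped.iterrows()]
    return AggregatedSeries(measure_id=measure_id, grain=grain, points=points)


def list_frequencies(log: ObservationLog, measure_id: str, grain: str = "phase",
                     schedule: Optional[Schedule] = None,
                     spec: Optional[TrialSpec] = None) -> list[FrequencyPoint]:
    """Per-item counts of a categorical measure, per day or per phase."""
    if grain not in ("day", "phase"):
        raise ValueError(f"grain must be 'day' or 'phase', got {grain!r}")
    if grain == "phase" and schedule is None:
        raise ValueError("phase-grain frequencies require the trial schedule")
    if spec is not None:
        measure = spec.measure_by_id(measure_id)
        if measure is not None and measure.input_type is not InputType.LIST:
            raise SummaryError(f"measure {measure_id!r} is not a list measure",
                               code="non_list_measure")
    buckets: dict[int, tuple[str, Counter]] = {}
    for o in log.for_measure(measure_id):
        if not isinstance(o.value, str):
            raise SummaryError(f"measure {measure_id!r} has numeric values",
                               code="non_list_measure")
        idx = (o.day_index if grain == "day"
               else phase_ordinal_on_day(schedule, o.day_index))
        label, counter = buckets.setdefault(idx, (o.phase_label, Counter()))
        counter[o.value] += 1
    return [FrequencyPoint(index=idx, phase_label=label, counts=dict(counter))
            for idx, (label, counter) in sorted(buckets.items())]


def phase_contrast(log: ObservationLog, measure_id: str,
                   with_test: bool = False) -> PhaseContrast:
    """Pooled A-vs-B comparison of a numeric measure.

    Requires at least one observation in each phase type; the Welch t-test
    additionally requires two per phase type.
    """
    values_a, values_b = [], []
    for o in log.for_measure(measure_id):
        if not isinstance(o.value, (int, float)) or isinstance(o.value, bool):
            raise SummaryError(f"measure {measure_id!r} is categorical; "
                               "phase contrast is undefined",
                               code="non_numeric_measure")
        (values_a if o.phase_label == "A" else values_b).append(float(o.value))
    minimum = 2 if with_test else 1
    if len(values_a) < minimum or len(values_b) < minimum:
        raise SummaryError(
            f"need >= {minimum} observation(s) per phase type, "
            f"got A:{len(values_a)} B:{len(values_b)}", code="insufficient_data")
    mean_a = sum(values_a) / len(values_a)
    mean_b = sum(values_b) / len(values_b)
    result = PhaseContrast(measure_id=measure_id, mean_a=mean_a, mean_b=mean_b,
                           difference=mean_a - mean_b,
                           n_a=len(values_a), n_b=len(values_b))
    if with_test:
        test = stats.ttest_ind(values_a, values_b, equal_var=False)
        result.t_statistic = float(test.statistic)
        result.df = float(test.df)
        result.p_value = float(test.pvalue)
    return result


def history_report(spec: TrialSpec, log: ObservationLog) -> dict:
    """Structured per-measure results: both grains plus the phase contrast.

    Measures without observations are reported with status ``"no data"``.
    The contrast carries a Welch test when both phase types have at least
    two observations, plain means when both have at least one, and is
    otherwise absent.
    """
    require_valid(spec)
    sections = []
    for m in spec.measures:
        n_obs = len(log.for_measure(m.id))
        section: dict = {
            "measure_id": m.id,
            "name": m.name,
            "input_type": m.input_type.value,
            "n_observations": n_obs,
            "status": "ok" if n_obs else "no data",
        }
        if n_obs:
            if m.input_type is InputType.LIST:
                section["frequencies_by_day"] = [
                    f.model_dump() for f in list_frequencies(log, m.id, "day")]
                section["frequencies_by_phase"] = [
                    f.model_dump() for f in
                    list_frequencies(log, m.id, "phase", schedule=spec.schedule)]
            else:
                section["by_day"] = aggregate(log, m.id, "day").model_dump()
                section["by_phase"] = aggregate(
                    log, m.id, "phase", schedule=spec.schedule).model_dump()
                try:
                    contrast = phase_contrast(log, m.id, with_test=True)
                except SummaryError:
                    try:
                        contrast = phase_contrast(log, m.id, with_test=False)
                    except SummaryError:
                        contrast = None
                if contrast is not None:
                    section["phase_contrast"] = contrast.model_dump()
        sections.append(section)
    return {"trial_id": spec.id, "design": spec.design.value,
            "measures": sections}


def render_report(report: dict) -> str:
    """Plain-text rendering of :func:`history_report` output."""
    lines = [f"Trial {report['trial_id']} ({report['design']})"]
    for m in report["measures"]:
        lines.append("")
        lines.append(f"Measure: {m['name']} [{m['input_type']}] — "
                     f"{m['n_observations']} observation(s)")
        if m["status"] == "no data":
            lines.append("  no data")
            continue
        if "by_phase" in m:
            for pt in m["by_phase"]["points"]:
                lines.append(f"  phase {pt['index']} ({pt['phase_label']}): "
                             f"mean {pt['mean']:.3f} over n={pt['n']}")
            c = m.get("phase_contrast")
            if c:
                line = (f"  contrast A−B: {c['difference']:.3f} "
                        f"(mean A {c['mean_a']:.3f}, n={c['n_a']}; "
                        f"mean B {c['mean_b']:.3f}, n={c['n_b']})")
                if c.get("t_statistic") is not None:
                    line += (f"; Welch t={c['t_statistic']:.3f}, "
                             f"df={c['df']:.1f}, p={c['p_value']:.4f}")
                lines.append(line)
        else:
            for pt in m["frequencies_by_phase"]:
                counts = ", ".join(f"{k}: {v}" for k, v in
                                   sorted(pt["counts"].items()))
                lines.append(f"  phase {pt['index']} ({pt['phase_label']}): {counts}")
    return "\n".join(lines)
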