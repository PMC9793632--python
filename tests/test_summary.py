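"""Aggregation, categorical frequencies, and the Welch phase contrast."""

import math
import random
from datetime import timedelta

import pytest
from hypothesis import given, strategies as st
from scipy import stats as scipy_stats

from nof1 import (
    InputType,
    Measure,
    ObservationLog,
    ReminderPolicy,
    Schedule,
    SummaryError,
    aggregate,
    history_report,
    list_frequencies,
    phase_contrast,
    record,
    render_report,
)
from conftest import CREATED, make_withdrawal_trial


def welch_by_hand(a, b):
    """Textbook Welch t: statistic, Welch–Satterthwaite df, two-sided p."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * scipy_stats.t.sf(abs(t), df)
    return t, df, p


def logged(spec, entries, measure_id=None):
    """entries: list of (day, value) recorded at noon of that day."""
    measure_id = measure_id or spec.measures[0].id
    log = ObservationLog()
    for day, value in entries:
        log.append(record(spec, measure_id, value,
                          at=CREATED.replace(hour=12) + timedelta(days=day - 1)))
    return log


class TestAggregate:
    def test_by_day_means(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 2), (1, 4), (2, 6)])
        series = aggregate(log, "m-pain", "day")
        assert [(p.index, p.mean, p.n) for p in series.points] == \
            [(1, 3.0, 2), (2, 6.0, 1)]

    def test_by_phase_pools_raw_values(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 2), (1, 4), (2, 6)])
        series = aggregate(log, "m-pain", "phase",
                           schedule=withdrawal_trial.schedule)
        assert len(series.points) == 1
        point = series.points[0]
        assert (point.index, point.phase_label) == (1, "A")
        assert point.mean == pytest.approx((2 + 4 + 6) / 3)  # not mean of daily means

    def test_empty_log_gives_empty_series(self, withdrawal_trial):
        series = aggregate(ObservationLog(), "m-pain", "day")
        assert series.points == []

    def test_days_without_data_omitted(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 2), (9, 6)])
        series = aggregate(log, "m-pain", "day")
        assert [p.index for p in series.points] == [1, 9]

    def test_list_measure_unsupported(self):
        spec = make_withdrawal_trial(measure=Measure(
            id="m-yn", name="yn", input_type=InputType.LIST,
            list_config={"items": ["yes", "no"]},
            reminder=ReminderPolicy(times=["20:00"])))
        log = logged(spec, [(1, "yes")], "m-yn")
        with pytest.raises(SummaryError) as err:
            aggregate(log, "m-yn", "day")
        assert err.value.code == "non_numeric_measure"

    @given(st.integers(0, 10**6))
    def test_phase_mean_equals_brute_force_pool(self, seed):
        rng = random.Random(seed)
        spec = make_withdrawal_trial(
            schedule=Schedule(phase_duration_days=rng.randint(1, 7),
                              n_phase_pairs=rng.randint(1, 4)))
        from nof1.scheduling import total_duration
        total = total_duration(spec.schedule)
        entries = [(rng.randint(1, total), rng.uniform(0, 10))
                   for _ in range(rng.randint(1, 40))]
        log = logged(spec, entries)
        d = spec.schedule.phase_duration_days
        series = aggregate(log, "m-pain", "phase", schedule=spec.schedule)
        for point in series.points:
            pooled = [v for day, v in entries if (day - 1) // d + 1 == point.index]
            assert point.n == len(pooled)
            assert point.mean == pytest.approx(sum(pooled) / len(pooled))


class TestListFrequencies:
    def _spec_and_log(self):
        spec = make_withdrawal_trial(measure=Measure(
            id="m-yn", name="yn", input_type=InputType.LIST,
            list_config={"items": ["yes", "no"]},
            reminder=ReminderPolicy(times=["20:00"])))
        log = logged(spec, [(1, "yes"), (2, "yes"), (3, "yes"), (4, "no"),
                            (9, "no")], "m-yn")
        return spec, log

    def test_counts_sum_to_observations_per_phase(self):
        spec, log = self._spec_and_log()
        points = list_frequencies(log, "m-yn", "phase", schedule=spec.schedule)
        assert points[0].counts == {"yes": 3, "no": 1}
        assert sum(points[0].counts.values()) == 4

    def test_empty_phases_omitted(self):
        spec, log = self._spec_and_log()
        points = list_frequencies(log, "m-yn", "phase", schedule=spec.schedule)
        assert [p.index for p in points] == [1, 2]  # phases 3, 4 have no data

    def test_counts_match_brute_force_tally(self):
        spec, log = self._spec_and_log()
        points = list_frequencies(log, "m-yn", "day")
        tally = {}
        for o in log:
            tally.setdefault(o.day_index, {}).setdefault(o.value, 0)
            tally[o.day_index][o.value] += 1
        assert {p.index: p.counts for p in points} == tally

    def test_numeric_measure_rejected(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 5)])
        with pytest.raises(SummaryError):
            list_frequencies(log, "m-pain", "day")


class TestPhaseContrast:
    def test_exact_difference(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 5), (2, 5), (8, 3), (9, 3)])
        c = phase_contrast(log, "m-pain")
        assert (c.mean_a, c.mean_b, c.difference) == (5.0, 3.0, 2.0)
        assert (c.n_a, c.n_b) == (2, 2)

    def test_identical_samples_give_zero_difference_and_t(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 4), (2, 6), (8, 4), (9, 6)])
        c = phase_contrast(log, "m-pain", with_test=True)
        assert c.difference == 0.0
        assert c.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_data_rejected(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 5)])  # nothing in any B phase
        with pytest.raises(SummaryError) as err:
            phase_contrast(log, "m-pain")
        assert err.value.code == "insufficient_data"
        log2 = logged(withdrawal_trial, [(1, 5), (8, 3)])
        with pytest.raises(SummaryError):
            phase_contrast(log2, "m-pain", with_test=True)

    @given(st.integers(0, 10**6))
    def test_welch_matches_textbook_formula(self, seed):
        rng = random.Random(seed)
        spec = make_withdrawal_trial()
        entries = [(rng.choice([1, 2, 3, 4, 5]), rng.uniform(0, 10))
                   for _ in range(rng.randint(2, 15))]
        entries += [(rng.choice([8, 9, 10, 11]), rng.uniform(0, 10))
                    for _ in range(rng.randint(2, 15))]
        log = logged(spec, entries)
        c = phase_contrast(log, "m-pain", with_test=True)
        a = [v for d, v in entries if d <= 7]
        b = [v for d, v in entries if d > 7]
        t, df, p = welch_by_hand(a, b)
        assert c.t_statistic == pytest.approx(t, abs=1e-10)
        assert c.df == pytest.approx(df, abs=1e-10)
        assert c.p_value == pytest.approx(p, abs=1e-10)
        assert c.difference == pytest.approx(c.mean_a - c.mean_b)


class TestHistoryReport:
    def test_empty_log_marks_measures_no_data(self, withdrawal_trial):
        report = history_report(withdrawal_trial, ObservationLog())
        assert [m["status"] for m in report["measures"]] == ["no data"]

    def test_one_measure_one_section(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 5), (8, 3)])
        report = history_report(withdrawal_trial, log)
        assert len(report["measures"]) == 1
        section = report["measures"][0]
        assert section["measure_id"] == "m-pain"

    def test_report_means_equal_aggregate(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 5), (1, 7), (8, 3)])
        report = history_report(withdrawal_trial, log)
        section = report["measures"][0]
        direct = aggregate(log, "m-pain", "day").model_dump()
        assert section["by_day"] == direct

    def test_contrast_downgrades_gracefully(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 5), (8, 3)])  # 1 obs per phase type
        report = history_report(withdrawal_trial, log)
        contrast = report["measures"][0]["phase_contrast"]
        assert contrast["difference"] == 2.0
        assert contrast["t_statistic"] is None

    def test_render_mentions_every_measure(self, withdrawal_trial):
        log = logged(withdrawal_trial, [(1, 5), (8, 3)])
        text = render_report(history_report(withdrawal_trial, log))
        assert "Pain level" in text and "contrast" in text
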