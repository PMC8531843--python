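"""Utilization-rate bookkeeping, aggregation and period statistics."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from lur.config_model import CalendarError, DegenerateError, DepartmentConfig, EmptyAggregateError
from lur.metrics import (
    DayMetrics,
    aggregate_metrics,
    day_metrics,
    entity_day_metrics,
    no_show_share,
    opening_hours,
    paired_signed_rank,
    summarize_period,
    weekly_opening_hours,
)

from conftest import (
    MONDAY,
    make_department,
    oracle_day_minutes,
    oracle_signed_rank_exact,
    random_day_events,
)
from test_config_model import _event


# -- opening hours ----------------------------------------------------------


def test_daily_opening_hours(study_department):
    assert opening_hours(study_department, "linac1", MONDAY) == 9.25
    assert opening_hours(study_department, "linac5", MONDAY) == 9.5
    with pytest.raises(CalendarError):
        opening_hours(study_department, "linac1", MONDAY + dt.timedelta(days=5))


def test_weekly_opening_hours(study_department):
    assert weekly_opening_hours(study_department) == 375.0
    assert weekly_opening_hours(study_department, "linac1") == 46.25
    assert weekly_opening_hours(study_department, "linac8") == 47.5
    assert weekly_opening_hours(DepartmentConfig(linacs=[])) == 0.0


# -- per-day metrics --------------------------------------------------------


def test_empty_day_is_all_zero(department):
    m = day_metrics([], department, "L1", MONDAY)
    assert (m.HT, m.HNT, m.LUR_T, m.LUR_NT, m.LUR) == (0, 0, 0, 0, 0)
    assert m.OH1 == 9.25


def test_treatment_past_closing_pushes_lur_t_above_100(study_department):
    # 9.5 h window fully treated plus 15 min running over after closing
    events = [
        _event(405, 975, linac="linac5"),  # 06:45-16:15
        _event(975, 990, linac="linac5"),  # 16:15-16:30
    ]
    m = day_metrics(events, study_department, "linac5", MONDAY)
    assert m.OH2_hours == 0.25
    assert m.LUR_T == pytest.approx(100 * 9.75 / 9.5)  # ≈ 102.6%
    assert m.LUR_T > 100


def test_no_show_excluded_from_ht_but_tracked(department):
    events = [_event(540, 600), _event(600, 660, no_show=True)]
    m = day_metrics(events, department, "L1", MONDAY)
    assert m.HT == 1.0
    assert m.no_show_hours == 1.0


def test_random_schedules_match_minute_grid_oracle(department):
    rng = np.random.default_rng(7)
    window = department.linac("L1").window(MONDAY)
    for _ in range(100):
        events = random_day_events(rng, "L1", MONDAY)
        m = day_metrics(events, department, "L1", MONDAY)
        ref = oracle_day_minutes(events, window)
        assert m.HT * 60 == pytest.approx(ref["HT"])
        assert m.HNT * 60 == pytest.approx(ref["HNT"])
        assert m.OH2_hours * 60 == pytest.approx(ref["OH2"])
        assert m.no_show_hours * 60 == pytest.approx(ref["no_show"])
        assert m.HT_prebooked * 60 == pytest.approx(ref["prebooked"])


# -- aggregation ------------------------------------------------------------


def _metrics(entity, oh1, lur_t):
    return DayMetrics.from_hours(entity, MONDAY, oh1, 0.0, lur_t * oh1 / 100, 0.0, 0.0, 0.0)


def test_homogeneous_aggregate_is_identity():
    ms = [_metrics(f"L{i}", 9.25, 80.0) for i in (1, 2, 3)]
    assert aggregate_metrics(ms, "park").LUR_T == pytest.approx(80.0)
    assert aggregate_metrics(ms, "park", "mean_of_linacs").LUR_T == pytest.approx(80.0)


def test_pooled_vs_mean_of_linacs():
    ms = [_metrics("A", 9.25, 100.0), _metrics("B", 9.5, 0.0)]
    pooled = aggregate_metrics(ms, "park")
    assert pooled.LUR_T == pytest.approx(100 * 9.25 / 18.75)  # ≈ 49.33
    mean = aggregate_metrics(ms, "park", "mean_of_linacs")
    assert mean.LUR_T == pytest.approx(50.0)


def test_pooled_park_equals_super_linac_oracle():
    """Pooling an 8-linac day equals treating the union as one linac."""
    dep = make_department(8)
    rng = np.random.default_rng(11)
    per_linac, union_minutes = [], {"HT": 0, "HNT": 0}
    window = dep.linac("L1").window(MONDAY)
    for lid in dep.linac_ids:
        events = random_day_events(rng, lid, MONDAY)
        per_linac.append(day_metrics(events, dep, lid, MONDAY))
        ref = oracle_day_minutes(events, window)
        union_minutes["HT"] += ref["HT"]
        union_minutes["HNT"] += ref["HNT"]
    pooled = aggregate_metrics(per_linac, "park")
    oh1_minutes = 8 * 555
    assert pooled.LUR_T == pytest.approx(100 * union_minutes["HT"] / oh1_minutes)
    assert pooled.LUR_NT == pytest.approx(100 * union_minutes["HNT"] / oh1_minutes)
    assert pooled.LUR == pooled.LUR_T + pooled.LUR_NT  # exact additivity


def test_empty_aggregate_raises():
    with pytest.raises(EmptyAggregateError):
        aggregate_metrics([], "park")


def test_entity_day_metrics_routes_events(department):
    events = [_event(540, 600, linac="L1"), _event(540, 660, linac="L2")]
    park = entity_day_metrics(events, department, "park", MONDAY)
    assert park.HT == pytest.approx(3.0)
    single = entity_day_metrics(events, department, "L2", MONDAY)
    assert single.HT == pytest.approx(2.0)


# -- weekly no-show share ---------------------------------------------------


def test_no_show_share_worked_example(study_department):
    # 2.2 no-show hours against the park's 375 weekly opening hours
    events = [
        _event(540, 540 + 132, linac="linac1", no_show=True),  # 2.2 h
    ]
    assert no_show_share(events, study_department, (2018, 10)) == 0.6
    assert no_show_share([], study_department, (2018, 10)) == 0.0


def test_no_show_share_recovers_injected_minutes(department):
    # dept weekly opening = 2 linacs * 46.25 = 92.5 h
    events = [
        _event(540, 600, no_show=True),  # Monday, 60 min
        _event(540, 585, date=MONDAY + dt.timedelta(days=2), linac="L2", no_show=True),
        _event(700, 760, date=MONDAY + dt.timedelta(days=7), no_show=True),  # next week
    ]
    expected = round(100 * (105 / 60) / 92.5, 1)
    assert no_show_share(events, department, (2018, 10)) == expected


# -- period summaries -------------------------------------------------------


def test_summarize_constant_and_simple_series():
    s = summarize_period([42.0] * 10)
    assert (s.mean, s.median, s.sd) == (42.0, 42.0, 0.0)
    s2 = summarize_period([0.0, 50.0, 100.0])
    assert (s2.mean, s2.median, s2.min, s2.max) == (50.0, 50.0, 0.0, 100.0)


def test_summarize_matches_two_pass_oracle():
    rng = np.random.default_rng(5)
    series = rng.normal(80, 12, size=424)
    s = summarize_period(series)
    # independent two-pass reference
    mean = sum(series) / len(series)
    var = sum((x - mean) ** 2 for x in series) / (len(series) - 1)
    assert s.mean == pytest.approx(mean)
    assert s.sd == pytest.approx(var**0.5)
    assert s.median == pytest.approx(float(np.sort(series)[211:213].mean()))
    assert s.n_days == 424


# -- Wilcoxon signed rank ---------------------------------------------------


def test_signed_rank_degenerate_when_identical():
    with pytest.raises(DegenerateError):
        paired_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_signed_rank_all_positive_n6_exact():
    planned = np.zeros(6)
    observed = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    assert paired_signed_rank(planned, observed) == pytest.approx(2 / 64)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_signed_rank_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    d = np.round(rng.normal(0.4, 1.0, size=10), 2)
    d = d[d != 0]
    p_pkg = paired_signed_rank(np.zeros(d.size), d)
    p_oracle = oracle_signed_rank_exact(d)
    if np.unique(np.abs(d)).size == d.size:  # exact path applies
        assert p_pkg == pytest.approx(p_oracle)
    else:  # approximate path must at least agree with oracle to 10%
        assert p_pkg == pytest.approx(p_oracle, abs=0.1)


def test_signed_rank_detects_large_shift():
    rng = np.random.default_rng(9)
    planned = rng.normal(80, 5, size=200)
    observed = planned + rng.normal(2.0, 1.0, size=200)
    assert paired_signed_rank(planned, observed) <= 0.05


def test_additivity_holds_on_random_days(department):
    rng = np.random.default_rng(13)
    for _ in range(200):
        m = day_metrics(random_day_events(rng, "L1", MONDAY), department, "L1", MONDAY)
        assert m.LUR == m.LUR_T + m.LUR_NT  # exact, not approx
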