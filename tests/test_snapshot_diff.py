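"""Planned-vs-observed Day-0 deviation counting and attribution."""

from __future__ import annotations

import datetime as dt
from dataclasses import replace

import numpy as np
import pytest

from lur.config_model import (
    NT_TIE_ORDER,
    Snapshot,
    SnapshotMismatchError,
    ZeroTotalError,
)
from lur.metrics import entity_day_metrics
from lur.snapshot_diff import (
    attribute_nt_increase,
    count_changes,
    deviation_frequency,
    diff_day0,
    nt_attribution_counts,
    percent_of_days,
)

from conftest import MONDAY, random_day_events
from test_config_model import _event


def _pair(planned_events, observed_events, date=MONDAY):
    planned = Snapshot(date, "planned", [replace(e, status="planned") for e in planned_events])
    observed = Snapshot(date, "observed", [replace(e, status="observed") for e in observed_events])
    return planned, observed


def _by_level(records, level):
    return [r for r in records if r.level == level]


# -- diff_day0 --------------------------------------------------------------


def test_identical_snapshots_give_zero_deltas(department):
    events = [_event(540, 600), _event(700, 760, linac="L2", sub="Break")]
    planned, observed = _pair(events, events)
    for rec in diff_day0(planned, observed, department):
        assert rec.delta_LUR == rec.delta_LUR_T == rec.delta_LUR_NT == 0.0
        assert rec.classification("LUR") == "none"
        assert not rec.deviated


def test_maintenance_doubling_raises_lur_nt(department):
    # 60 min planned maintenance grows to 120 min on a 9.25 h linac
    planned, observed = _pair(
        [_event(540, 600, sub="Maintenance")],
        [_event(540, 660, sub="Maintenance")],
    )
    rec = [r for r in diff_day0(planned, observed, department) if r.entity_id == "L1"][0]
    assert rec.delta_LUR_NT == pytest.approx(100 * 60 / 555)  # ≈ +10.81 pp
    assert rec.classification("LUR_NT") == "increase"
    assert rec.delta_LUR == rec.delta_LUR_T + rec.delta_LUR_NT


def test_snapshot_mismatch_errors(department):
    planned, observed = _pair([], [])
    bad_date = Snapshot(MONDAY + dt.timedelta(days=1), "observed", [])
    with pytest.raises(SnapshotMismatchError):
        diff_day0(planned, bad_date, department)
    with pytest.raises(SnapshotMismatchError):
        diff_day0(observed, observed, department)  # wrong kinds


def test_park_delta_equals_pooled_recomputation_oracle(department):
    rng = np.random.default_rng(21)
    p_events, o_events = [], []
    for lid in department.linac_ids:
        p_events += random_day_events(rng, lid, MONDAY, no_show_prob=0)
        o_events += random_day_events(rng, lid, MONDAY, no_show_prob=0)
    planned, observed = _pair(p_events, o_events)
    park = [r for r in diff_day0(planned, observed, department) if r.level == "park"][0]
    m_p = entity_day_metrics(planned.events, department, "park", MONDAY)
    m_o = entity_day_metrics(observed.events, department, "park", MONDAY)
    assert park.delta_LUR_T == pytest.approx(m_o.LUR_T - m_p.LUR_T)
    assert park.delta_LUR_NT == pytest.approx(m_o.LUR_NT - m_p.LUR_NT)


def test_swapping_snapshots_negates_all_deltas(department):
    rng = np.random.default_rng(22)
    a = random_day_events(rng, "L1", MONDAY, no_show_prob=0)
    b = random_day_events(rng, "L1", MONDAY, no_show_prob=0)
    fwd = diff_day0(*_pair(a, b), department)
    rev = diff_day0(*_pair(b, a), department)
    for f, r in zip(fwd, rev):
        assert f.entity_id == r.entity_id
        assert f.delta_ht_minutes == -r.delta_ht_minutes
        assert f.delta_hnt_minutes == -r.delta_hnt_minutes
        inc_f, dec_f, none_f = count_changes([f], "LUR")
        inc_r, dec_r, none_r = count_changes([r], "LUR")
        assert (inc_f, dec_f, none_f) == (dec_r, inc_r, none_r)


# -- counting ---------------------------------------------------------------


def test_count_changes_partitions(department):
    planned, observed = _pair(
        [_event(540, 600), _event(540, 600, linac="L2")],
        [_event(540, 660), _event(540, 600, linac="L2")],
    )
    recs = _by_level(diff_day0(planned, observed, department), "linac")
    n_inc, n_dec, n_none = count_changes(recs, "LUR_T")
    assert (n_inc, n_dec, n_none) == (1, 0, 1)
    assert n_inc + n_dec + n_none == len(recs)


@pytest.mark.parametrize(
    "count,total,expected",
    [(745, 3390, 22), (1343, 3390, 40), (1454, 3390, 43),
     (1150, 3390, 34), (124, 3390, 4), (985, 3390, 29), (0, 100, 0)],
)
def test_percent_of_days_rounds_half_away_from_zero(count, total, expected):
    assert percent_of_days(count, total) == expected


def test_percent_of_days_zero_total():
    with pytest.raises(ZeroTotalError):
        percent_of_days(0, 0)


# -- attribution ------------------------------------------------------------


def test_attribution_argmax_and_threshold(department):
    planned, observed = _pair(
        [],
        [_event(540, 660, sub="Maintenance"), _event(700, 705, sub="PatientQA")],
    )
    rec = _by_level(diff_day0(planned, observed, department), "linac")[0]
    assert attribute_nt_increase(rec, 5.0) == "Maintenance"
    # a 1.5 pp increase is below a 2 pp threshold
    planned2, observed2 = _pair([], [_event(540, 548, sub="PatientQA")])  # 8 min ≈ 1.44 pp
    rec2 = _by_level(diff_day0(planned2, observed2, department), "linac")[0]
    assert attribute_nt_increase(rec2, 2.0) is None
    assert attribute_nt_increase(rec2, 0.0) == "PatientQA"


def test_attribution_matches_bruteforce_with_tie_order(department):
    rng = np.random.default_rng(33)
    for _ in range(200):
        deltas = {s: int(rng.integers(-60, 61)) for s in NT_TIE_ORDER}
        d_hnt = sum(deltas.values())
        from lur.snapshot_diff import DeltaRecord

        rec = DeltaRecord(
            entity_id="L1", level="linac", date=MONDAY, oh1_minutes=555,
            delta_ht_minutes=0, delta_hnt_minutes=d_hnt,
            delta_LUR_T=0.0, delta_LUR_NT=100 * d_hnt / 555,
            delta_LUR=100 * d_hnt / 555, category_deltas=deltas,
        )
        got = attribute_nt_increase(rec, 0.0)
        if d_hnt <= 0:
            assert got is None
        else:
            best = max(
                (s for s in NT_TIE_ORDER if deltas[s] > 0),
                key=lambda s: (deltas[s], -NT_TIE_ORDER.index(s)),
                default=None,
            )
            assert got == best


def test_attribution_thresholds_nest(department):
    rng = np.random.default_rng(44)
    records = []
    for day in range(40):
        date = MONDAY + dt.timedelta(weeks=day)
        p = random_day_events(rng, "L1", date, no_show_prob=0)
        o = random_day_events(rng, "L1", date, no_show_prob=0)
        records += diff_day0(*_pair(p, o, date), department)
    sets = {}
    for t in (0.0, 2.0, 5.0):
        sets[t] = {
            (r.entity_id, r.date)
            for r in _by_level(records, "linac")
            if attribute_nt_increase(r, t) is not None
        }
    assert sets[5.0] <= sets[2.0] <= sets[0.0]
    # the summary table reflects the same nesting
    table = nt_attribution_counts(records)
    assert table[5.0]["n_attributed"] <= table[2.0]["n_attributed"] <= table[0.0]["n_attributed"]


# -- deviation frequency ----------------------------------------------------


def test_deviation_frequency_extremes(department):
    quiet, busy = [], []
    for day in range(10):
        date = MONDAY + dt.timedelta(weeks=day)
        base = [_event(540, 600, date=date)]
        quiet += diff_day0(*_pair(base, base, date), department)
        busy += diff_day0(*_pair(base, base + [_event(700, 760, date=date)], date), department)
    assert deviation_frequency(quiet, "linac") == 0
    assert deviation_frequency(busy, "park") == 100


def test_linac_deviation_implies_park_deviation_one_sided(department):
    """With one-sided (additive) perturbations deltas cannot cancel, so a
    deviating linac forces a deviating park record on the same date."""
    rng = np.random.default_rng(55)
    for day in range(20):
        date = MONDAY + dt.timedelta(weeks=day)
        p, o = [], []
        for lid in department.linac_ids:
            base = random_day_events(rng, lid, date, no_show_prob=0)
            p += base
            o += base
            if rng.random() < 0.5:  # additive-only perturbation
                o.append(_event(int(rng.integers(360, 900)), 1000, linac=lid,
                                date=date, sub="Maintenance"))
        recs = diff_day0(*_pair(p, o, date), department)
        linac_dev = any(r.deviated for r in _by_level(recs, "linac"))
        park_dev = _by_level(recs, "park")[0].deviated
        assert park_dev == linac_dev
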