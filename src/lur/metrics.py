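"""Linac utilization rate (LUR) metrics.

For one linac and one day the bookkeeping variables are

* ``OH1`` — the linac's opening hours (window length),
* ``OH2`` — scheduled activity time falling *outside* the opening window,
* ``HT``  — hours dedicated to patient treatment (the ``Pre-booked`` and
  ``Treatment`` subcategories), inside *and* outside opening hours,
  excluding no-shows,
* ``HNT`` — hours of non-treatment activity *within* opening hours only.

The utilization rates are then

.. math::

    LUR_T = 100 \\cdot HT / OH_1, \\qquad
    LUR_{NT} = 100 \\cdot HNT / OH_1, \\qquad
    LUR = LUR_T + LUR_{NT}.

``LUR_T`` may exceed 100% when treatments extend past closing time
(``OH2`` minutes still count toward ``HT``); ``LUR_NT`` cannot, because
``HNT`` is clipped to the opening window.  All sums are exact integer
minutes; rates are formed only at the end.

The module also provides aggregation over treatment-equivalent linac
groups and the whole machine park, period summaries (mean/SD/median/range)
and the paired Wilcoxon signed-rank comparison of planned vs observed
daily rates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config_model import (
    NON_TREATMENT_SUBCATEGORIES,
    TREATMENT,
    TREATMENT_SUBCATEGORIES,
    CalendarError,
    DegenerateError,
    DepartmentConfig,
    EmptyAggregateError,
    ScheduleEvent,
    clip_to_window,
)

__all__ = [
    "DayMetrics",
    "PeriodSummary",
    "opening_hours",
    "weekly_opening_hours",
    "category_minutes",
    "day_metrics",
    "aggregate_metrics",
    "no_show_share",
    "summarize_period",
    "paired_signed_rank",
    "metrics_to_frame",
]

METRIC_NAMES = ("LUR_T", "LUR_NT", "LUR", "LUR_prebooked")


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class DayMetrics:
    """Per entity-day utilization bookkeeping (hours) and rates (percent).

    ``entity_id`` is a linac id, a group id, or ``"park"``.  ``LUR`` is
    stored as ``LUR_T + LUR_NT`` so the additivity identity holds exactly
    for every record, pooled or not.
    """

    entity_id: str
    date: dt.date
    OH1: float
    OH2_hours: float
    HT: float
    HNT: float
    HT_prebooked: float
    no_show_hours: float
    LUR_T: float
    LUR_NT: float
    LUR: float
    LUR_prebooked: float

    @classmethod
    def from_hours(
        cls,
        entity_id: str,
        date: dt.date,
        oh1: float,
        oh2: float,
        ht: float,
        hnt: float,
        ht_prebooked: float,
        no_show: float,
    ) -> "DayMetrics":
        if oh1 <= 0:
            raise ValueError("OH1 must be positive")
        lur_t = 100.0 * ht / oh1
        lur_nt = 100.0 * hnt / oh1
        return cls(
            entity_id=entity_id,
            date=date,
            OH1=oh1,
            OH2_hours=oh2,
            HT=ht,
            HNT=hnt,
            HT_prebooked=ht_prebooked,
            no_show_hours=no_show,
            LUR_T=lur_t,
            LUR_NT=lur_nt,
            LUR=lur_t + lur_nt,
            LUR_prebooked=100.0 * ht_prebooked / oh1,
        )

    def value(self, metric: str) -> float:
        if metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
        return getattr(self, metric)


@dataclass(frozen=True, slots=True)
class PeriodSummary:
    """Distributional summary of one daily-percent series over a period."""

    entity_id: str
    metric: str
    mean: float
    sd: float
    median: float
    min: float
    max: float
    n_days: int


# --------------------------------------------------------------------------
# Opening-hours arithmetic
# --------------------------------------------------------------------------


def opening_hours(config: DepartmentConfig, linac_id: str, date: dt.date) -> float:
    """Daily opening hours of one linac: ``(close - open) / 60``."""
    if not config.is_open_day(date):
        raise CalendarError(f"{date} is not an operating day")
    lo, hi = config.linac(linac_id).window(date)
    return (hi - lo) / 60.0


def weekly_opening_hours(config: DepartmentConfig, linac_id: str | None = None) -> float:
    """Opening hours per week, summed Mon-Fri, for one linac or the park."""
    linacs = [config.linac(linac_id)] if linac_id is not None else config.linacs
    total_minutes = sum(
        hi - lo for l in linacs for (lo, hi) in l.weekday_windows.values()
    )
    return total_minutes / 60.0


# --------------------------------------------------------------------------
# Per-day metrics
# --------------------------------------------------------------------------


def category_minutes(
    events: Sequence[ScheduleEvent],
    config: DepartmentConfig,
    linac_id: str,
    date: dt.date,
) -> dict[str, int]:
    """Effective scheduled minutes per subcategory for one linac-day.

    Treatment subcategories count their full duration (inside and outside
    the opening window) with no-show slots excluded; non-treatment
    subcategories count only minutes inside the window.  Two synthetic
    keys are added: ``"no_show"`` (full minutes of no-show slots) and
    ``"oh2"`` (all scheduled minutes outside the window, any category).
    """
    window = config.linac(linac_id).window(date)
    minutes = {sub: 0 for sub in TREATMENT_SUBCATEGORIES + NON_TREATMENT_SUBCATEGORIES}
    minutes["no_show"] = 0
    minutes["oh2"] = 0
    for ev in events:
        if ev.linac_id != linac_id or ev.date != date:
            raise ValueError(f"event not on ({linac_id}, {date}): {ev}")
        within, outside = clip_to_window(ev, window)
        minutes["oh2"] += outside
        if ev.main_category == TREATMENT:
            if ev.no_show:
                minutes["no_show"] += ev.duration
            else:
                minutes[ev.subcategory] += ev.duration
        else:
            minutes[ev.subcategory] += within
    return minutes


def day_metrics(
    events: Sequence[ScheduleEvent],
    config: DepartmentConfig,
    linac_id: str,
    date: dt.date,
) -> DayMetrics:
    """Compute one linac-day's :class:`DayMetrics` from its events."""
    cat = category_minutes(events, config, linac_id, date)
    lo, hi = config.linac(linac_id).window(date)
    ht_min = sum(cat[s] for s in TREATMENT_SUBCATEGORIES)
    hnt_min = sum(cat[s] for s in NON_TREATMENT_SUBCATEGORIES)
    return DayMetrics.from_hours(
        entity_id=linac_id,
        date=date,
        oh1=(hi - lo) / 60.0,
        oh2=cat["oh2"] / 60.0,
        ht=ht_min / 60.0,
        hnt=hnt_min / 60.0,
        ht_prebooked=cat["Pre-booked"] / 60.0,
        no_show=cat["no_show"] / 60.0,
    )


def aggregate_metrics(
    day_metrics_list: Sequence[DayMetrics],
    entity_id: str,
    method: Literal["pooled", "mean_of_linacs"] = "pooled",
) -> DayMetrics:
    """Aggregate same-date per-linac metrics to a group or the park.

    ``pooled`` (default) sums hours across linacs and recomputes the rates
    from the sums — the group behaves as one super-linac, which is the
    natural reading of a time-ratio.  ``mean_of_linacs`` takes the
    unweighted mean of the per-linac rates (and of the hour fields).
    """
    if not day_metrics_list:
        raise EmptyAggregateError("no per-linac metrics to aggregate")
    dates = {m.date for m in day_metrics_list}
    if len(dates) != 1:
        raise ValueError(f"aggregation mixes dates: {sorted(dates)}")
    date = dates.pop()
    if method == "pooled":
        return DayMetrics.from_hours(
            entity_id=entity_id,
            date=date,
            oh1=sum(m.OH1 for m in day_metrics_list),
            oh2=sum(m.OH2_hours for m in day_metrics_list),
            ht=sum(m.HT for m in day_metrics_list),
            hnt=sum(m.HNT for m in day_metrics_list),
            ht_prebooked=sum(m.HT_prebooked for m in day_metrics_list),
            no_show=sum(m.no_show_hours for m in day_metrics_list),
        )
    if method == "mean_of_linacs":
        n = len(day_metrics_list)
        mean = lambda attr: sum(getattr(m, attr) for m in day_metrics_list) / n
        lur_t = mean("LUR_T")
        lur_nt = mean("LUR_NT")
        return DayMetrics(
            entity_id=entity_id,
            date=date,
            OH1=mean("OH1"),
            OH2_hours=mean("OH2_hours"),
            HT=mean("HT"),
            HNT=mean("HNT"),
            HT_prebooked=mean("HT_prebooked"),
            no_show_hours=mean("no_show_hours"),
            LUR_T=lur_t,
            LUR_NT=lur_nt,
            LUR=lur_t + lur_nt,
            LUR_prebooked=mean("LUR_prebooked"),
        )
    raise ValueError(f"unknown aggregation method {method!r}")


def entity_day_metrics(
    events: Sequence[ScheduleEvent],
    config: DepartmentConfig,
    entity_id: str,
    date: dt.date,
    method: Literal["pooled", "mean_of_linacs"] = "pooled",
) -> DayMetrics:
    """Convenience: per-linac metrics for an entity's members, aggregated."""
    members = config.entity_members(entity_id)
    by_linac = {m: [] for m in members}
    for ev in events:
        if ev.date == date and ev.linac_id in by_linac:
            by_linac[ev.linac_id].append(ev)
    per_linac = [day_metrics(evs, config, lid, date) for lid, evs in by_linac.items()]
    if len(per_linac) == 1:
        return per_linac[0]
    return aggregate_metrics(per_linac, entity_id=entity_id, method=method)


# --------------------------------------------------------------------------
# Weekly no-show share
# --------------------------------------------------------------------------


def no_show_share(
    events: Sequence[ScheduleEvent],
    config: DepartmentConfig,
    week: tuple[int, int],
) -> float:
    """Share of weekly opening hours lost to no-shows, rounded to 0.1%.

    ``week`` is ``(iso_year, iso_week)``; events outside that week are
    ignored, so a full archive can be passed directly.
    """
    iso_year, iso_week = week
    ns_minutes = sum(
        ev.duration
        for ev in events
        if ev.no_show and ev.date.isocalendar()[:2] == (iso_year, iso_week)
    )
    weekly = weekly_opening_hours(config)
    return round(100.0 * (ns_minutes / 60.0) / weekly, 1)


# --------------------------------------------------------------------------
# Period summaries and planned/observed comparison
# --------------------------------------------------------------------------


def summarize_period(
    values: Sequence[float], entity_id: str = "", metric: str = ""
) -> PeriodSummary:
    """Mean, SD (n-1 denominator), median, min, max of a daily series."""
    if len(values) < 1:
        raise ValueError("summarize_period needs at least one day")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PeriodSummary(
        entity_id=entity_id,
        metric=metric,
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        n_days=int(arr.size),
    )


def paired_signed_rank(
    planned_daily: Sequence[float], observed_daily: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired daily rates.

    Zero differences are dropped (classic Wilcoxon zero handling); tied
    absolute differences receive mid-ranks.  The exact null distribution
    is used for n <= 25 pairs without ties, otherwise the normal
    approximation with continuity correction.
    """
    p = np.asarray(planned_daily, dtype=float)
    o = np.asarray(observed_daily, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("series must be equal-length 1-D with n >= 1")
    d = o - p
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=True,
        alternative="two-sided",
        method=method,
    )
    return float(res.pvalue)


def metrics_to_frame(records: Iterable[DayMetrics]) -> pd.DataFrame:
    """Tabular export: one row per entity-day, hours and percent columns."""
    rows = [
        (
            m.entity_id,
            m.date.isoformat(),
            m.OH1,
            m.OH2_hours,
            m.HT,
            m.HNT,
            m.HT_prebooked,
            m.no_show_hours,
            m.LUR_T,
            m.LUR_NT,
            m.LUR,
        )
        for m in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "entity_id",
            "date",
            "OH1",
            "OH2_hours",
            "HT",
            "HNT",
            "HT_prebooked",
            "no_show_hours",
            "LUR_T",
            "LUR_NT",
            "LUR",
        ],
    )
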