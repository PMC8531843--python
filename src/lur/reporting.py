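"""The tool's three user-facing views: daily, weekly, waiting patients.

* the *daily* view is an overview of scheduled treatment/non-treatment
  hours and utilization rates per linac, per treatment-equivalent group
  and for the whole machine park on one date;
* the *weekly* view counts new patients whose first fraction falls in an
  ISO week, in total and for the two largest diagnosis groups;
* the *waiting* view lists referred patients who are not yet scheduled,
  by their requested starting week.

Views are pure functions of the snapshot archive and the referral table;
percent values are rounded to integers at render time only, the raw
values stay available in the machine-readable output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config_model import DepartmentConfig, Snapshot, load_snapshot
from .metrics import DayMetrics, aggregate_metrics, day_metrics
from .simulate import ReferralRecord

__all__ = ["DailyView", "WeeklyView", "WaitingView", "daily_view", "weekly_view", "waiting_view"]


@dataclass(frozen=True)
class DailyView:
    date: dt.date
    rows: tuple[DayMetrics, ...]  # linacs, then groups, then park

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        data = [
            {
                "entity_id": m.entity_id,
                "treatment_hours": m.HT,
                "non_treatment_hours": m.HNT,
                "LUR_T": round(m.LUR_T) if rounded else m.LUR_T,
                "LUR_NT": round(m.LUR_NT) if rounded else m.LUR_NT,
                "LUR": round(m.LUR) if rounded else m.LUR,
            }
            for m in self.rows
        ]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class WeeklyView:
    iso_week: tuple[int, int]
    new_starts_total: int
    new_starts_by_group: dict[str, int]  # the two largest diagnosis groups
    scheduled_hours: float

    def to_frame(self) -> pd.DataFrame:
        row = {
            "iso_week": f"{self.iso_week[0]}-W{self.iso_week[1]:02d}",
            "new_starts_total": self.new_starts_total,
            "scheduled_hours": self.scheduled_hours,
        }
        for g, n in self.new_starts_by_group.items():
            row[f"new_starts_{g}"] = n
        return pd.DataFrame([row])


@dataclass(frozen=True)
class WaitingView:
    rows: tuple[ReferralRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "diagnosis_group": r.diagnosis_group,
                    "requested_start_week": "{}-W{:02d}".format(
                        *r.preferred_start.isocalendar()[:2]
                    ),
                    "n_fractions": r.n_fractions,
                }
                for r in self.rows
            ],
            columns=["patient_id", "diagnosis_group", "requested_start_week", "n_fractions"],
        )


def _resolve_snapshot(
    archive: str | Path | Snapshot, config: DepartmentConfig, date: dt.date
) -> Snapshot:
    if isinstance(archive, Snapshot):
        return archive
    return load_snapshot(archive, date, "planned", config)


def daily_view(
    archive: str | Path | Snapshot, config: DepartmentConfig, date: dt.date
) -> DailyView:
    """Scheduled hours and rates per linac/group/park for one date.

    Uses the planned snapshot taken on that date (Day-0 events).  The
    park row is the pooled aggregation of the linac rows.
    """
    snap = _resolve_snapshot(archive, config, date)
    events = snap.events_on(date)
    per_linac = {
        lid: day_metrics([e for e in events if e.linac_id == lid], config, lid, date)
        for lid in config.linac_ids
    }
    rows: list[DayMetrics] = list(per_linac.values())
    for gid in config.group_ids:
        rows.append(
            aggregate_metrics(
                [per_linac[m] for m in config.group_members(gid)], entity_id=gid
            )
        )
    rows.append(aggregate_metrics(list(per_linac.values()), entity_id="park"))
    return DailyView(date=date, rows=tuple(rows))


def weekly_view(
    archive: str | Path | Snapshot,
    referrals: Sequence[ReferralRecord],
    week: tuple[int, int],
    config: DepartmentConfig | None = None,
) -> WeeklyView:
    """New treatment starts and scheduled treatment hours for one ISO week.

    A patient counts once, in the ISO week of their series' first
    fraction (``fraction_no == 1``).  Events are read from the planned
    snapshot closest before the week (so the week is fully covered by the
    booking state at its start); pass a :class:`Snapshot` directly to
    control this.
    """
    iso_year, iso_week = week
    if isinstance(archive, Snapshot):
        snap = archive
    else:
        snap_date = _snapshot_date_for_week(archive, week)
        snap = load_snapshot(archive, snap_date, "planned", config)
    week_events = [
        e for e in snap.events if e.date.isocalendar()[:2] == (iso_year, iso_week)
    ]
    starters = {
        e.patient_id
        for e in week_events
        if e.fraction_no == 1 and e.patient_id is not None
    }
    by_group: dict[str, int] = {}
    diagnosis = {r.patient_id: r.diagnosis_group for r in referrals}
    for pid in starters:
        g = diagnosis.get(pid)
        if g is not None:
            by_group[g] = by_group.get(g, 0) + 1
    top2 = dict(sorted(by_group.items(), key=lambda kv: (-kv[1], kv[0]))[:2])
    scheduled_hours = (
        sum(e.duration for e in week_events if e.main_category == "Treatment" and not e.no_show)
        / 60.0
    )
    return WeeklyView(
        iso_week=week,
        new_starts_total=len(starters),
        new_starts_by_group=top2,
        scheduled_hours=scheduled_hours,
    )


def _snapshot_date_for_week(archive: str | Path, week: tuple[int, int]) -> dt.date:
    from .config_model import MissingSnapshotError, list_snapshot_dates

    monday = dt.date.fromisocalendar(week[0], week[1], 1)
    candidates = [d for d in list_snapshot_dates(archive, "planned") if d <= monday]
    if not candidates:
        raise MissingSnapshotError(f"no planned snapshot on or before {monday}")
    return candidates[-1]


def waiting_view(referrals: Sequence[ReferralRecord]) -> WaitingView:
    """Not-yet-scheduled referrals, sorted by requested start week then id."""
    waiting = [r for r in referrals if not r.scheduled]
    waiting.sort(key=lambda r: (r.preferred_start.isocalendar()[:2], r.patient_id))
    return WaitingView(rows=tuple(waiting))
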