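"""Synthetic radiotherapy department simulator.

Generates seeded, reproducible snapshot archives with the statistical
structure the analysis modules assume:

* patient referrals arrive as a Poisson stream per weekday; each brings a
  treatment series of consecutive-weekday fractions (mean 12.2 per
  series) with a 15–20 min slot, booked greedily on the earliest feasible
  run of days on one linac of one treatment-equivalent group;
* the booking *lead time* (weekdays between the referral and the first
  fraction) follows a logistic distribution, so the occupancy of any
  future date seen from h weekdays out traces a logistic fill curve with
  one steepest-growth region;
* a configurable share of each day is held by pre-booked care-path
  placeholder slots, created far in advance and converted to scheduled
  treatments as the date approaches;
* a stable non-treatment baseline (morning linac QA, breaks, meetings)
  occupies a flat share of opening hours;
* each simulated day's observed schedule perturbs the morning plan:
  maintenance/downtime blocks (displacing booked treatments), patient-QA
  insertions, treatment cancellations and rare no-shows (a configured
  fraction of opening hours, default 0.6%).

Every injected perturbation, booking lead and no-show is recorded in a
ground-truth ledger so analysis results can be checked against what the
simulator actually did.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .config_model import (
    NON_TREATMENT,
    TREATMENT,
    DepartmentConfig,
    LinacConfig,
    ScheduleEvent,
    Snapshot,
    snapshot_path,
    weekday_horizon,
    write_events_csv,
)

__all__ = [
    "default_department",
    "SimulationParams",
    "ReferralRecord",
    "SimulationResult",
    "simulate_referrals",
    "perturb_day",
    "run_simulation",
]


def default_department() -> DepartmentConfig:
    """An eight-linac park in three treatment-equivalent groups.

    Four linacs open 07:00–16:15 (9.25 h/day) and four open 06:45–16:15
    (9.5 h/day), Monday to Friday — 375 opening hours per week in total.
    """
    def _windows(open_hhmm: str) -> dict[str, tuple[str, str]]:
        return {k: (open_hhmm, "16:15") for k in ("Mon", "Tue", "Wed", "Thu", "Fri")}

    linacs = [
        LinacConfig(linac_id=f"linac{i}", group_id="group1", weekday_windows=_windows("07:00"))
        for i in range(1, 5)
    ]
    linacs += [
        LinacConfig(linac_id=f"linac{i}", group_id="group2", weekday_windows=_windows("06:45"))
        for i in (5, 6)
    ]
    linacs += [
        LinacConfig(linac_id=f"linac{i}", group_id="group3", weekday_windows=_windows("06:45"))
        for i in (7, 8)
    ]
    return DepartmentConfig(linacs=linacs)


#: Anchor start times (minutes from midnight) for baseline non-treatment
#: blocks; blocks are shifted forward minimally if anchors collide.
NT_ANCHORS: dict[str, int] = {
    "LinacQA": -1,  # -1: at the opening of the linac's window
    "Preparation": 10 * 60,
    "Break": 12 * 60,
    "Education": 14 * 60,
    "PatientQA": 14 * 60 + 30,
    "Meetings": 15 * 60 + 30,
}


class SimulationParams(BaseModel):
    """Tunable study conditions for the synthetic department.

    Defaults emulate the modelled clinic: ~14 referrals per weekday on an
    eight-linac park, 12.2 fractions per series, 15–20 min slots, a
    logistic booking build-up with midpoint 50 weekdays, a pre-booked
    share of 20% at the 100-day horizon converting to treatments near the
    date, a flat ~8% non-treatment baseline and 0.6% of opening hours
    lost to no-shows.
    """

    department: DepartmentConfig = Field(default_factory=default_department)
    start_date: dt.date = dt.date(2018, 2, 26)  # a Monday
    n_days: int = 424  # weekdays with a planned+observed snapshot pair
    referral_rate: float = 14.0  # patients per weekday
    mean_fractions: float = 12.2  # fractions per series (1 + Poisson)
    slot_minutes: tuple[int, int] = (15, 20)
    fill_midpoint_days: float = 50.0
    fill_steepness: float = 8.0
    prebooked_share_at_horizon: float = 20.0  # percent of OH1 at h = horizon
    prebooked_convert_midpoint: float = 30.0
    prebooked_convert_steepness: float = 6.8
    nt_baseline: dict[str, int] = Field(
        default_factory=lambda: {"LinacQA": 20, "Break": 15, "Meetings": 10}
    )
    maintenance_prob: float = 0.05  # per linac-day
    maintenance_minutes: int = 120
    patient_qa_prob: float = 0.35  # per linac-day
    patient_qa_minutes: int = 10
    cancellation_prob: float = 0.03  # per booked treatment slot
    no_show_rate: float = 0.006  # fraction of opening hours
    diagnosis_groups: dict[str, float] = Field(
        default_factory=lambda: {
            "breast": 0.30,
            "prostate": 0.28,
            "lung": 0.16,
            "head-neck": 0.11,
            "palliative": 0.15,
        }
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        for name in (
            "maintenance_prob",
            "patient_qa_prob",
            "cancellation_prob",
            "no_show_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.slot_minutes
        if not 0 < lo <= hi:
            raise ValueError("slot_minutes must be a positive (lo, hi) range")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.start_date.weekday() >= 5:
            raise ValueError("start_date must be a weekday")
        if self.mean_fractions < 1:
            raise ValueError("mean_fractions must be >= 1")
        if any(m <= 0 for m in self.nt_baseline.values()):
            raise ValueError("nt_baseline minutes must be positive")
        if abs(sum(self.diagnosis_groups.values()) - 1.0) > 1e-9:
            raise ValueError("diagnosis_groups probabilities must sum to 1")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))


@dataclass
class ReferralRecord:
    """One referred patient awaiting or holding a treatment series."""

    patient_id: str
    diagnosis_group: str
    referral_date: dt.date
    preferred_start: dt.date
    n_fractions: int
    slot_minutes: int
    scheduled: bool = False


@dataclass(slots=True)
class _Slot:
    """Internal booked slot on the (linac, weekday-index) grid."""

    linac_id: str
    day: int
    start: int
    end: int
    kind: str  # "regular" | "prebooked"
    booked_day: int  # weekday index when the slot entered the schedule
    convert_lead: float  # prebooked only: h below which it shows as Treatment
    patient_id: str | None = None
    series_id: str | None = None
    fraction_no: int | None = None


# --------------------------------------------------------------------------
# Referral stream
# --------------------------------------------------------------------------


def _draw_referrals(
    params: SimulationParams,
    rng: np.random.Generator,
    first_day: int,
    last_day: int,
    day_to_date,
) -> list[tuple[int, int, ReferralRecord]]:
    """Referrals for weekday indices [first_day, last_day); returns
    (referral_day, preferred_day, record) triples in arrival order."""
    H = params.department.horizon_weekdays
    groups = sorted(params.diagnosis_groups)
    probs = np.array([params.diagnosis_groups[g] for g in groups])
    out = []
    counter = 0
    for r in range(first_day, last_day):
        for _ in range(int(rng.poisson(params.referral_rate))):
            counter += 1
            lead = int(round(rng.logistic(params.fill_midpoint_days, params.fill_steepness)))
            lead = int(np.clip(lead, 1, H - 1))
            n_frac = 1 + int(rng.poisson(params.mean_fractions - 1.0))
            # centre the series on the drawn lead so the mean booking lead of
            # its slots (which trail the first fraction) matches the fill model
            lead = max(1, int(round(lead - (n_frac - 1) / 2.0)))
            lo, hi = params.slot_minutes
            rec = ReferralRecord(
                patient_id=f"p{counter:05d}",
                diagnosis_group=str(rng.choice(groups, p=probs)),
                referral_date=day_to_date(r),
                preferred_start=day_to_date(min(r + lead, last_day + H)),
                n_fractions=n_frac,
                slot_minutes=int(rng.integers(lo, hi + 1)),
            )
            out.append((r, r + lead, rec))
    return out


def simulate_referrals(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> list[ReferralRecord]:
    """Standalone referral stream for the snapshot period (seeded)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    calendar = weekday_horizon(
        params.start_date,
        params.n_days + params.department.horizon_weekdays + 1,
        params.department.holidays,
    )
    triples = _draw_referrals(params, rng, 0, params.n_days, lambda i: calendar[i])
    return [rec for _, _, rec in triples]


# --------------------------------------------------------------------------
# Booking grid
# --------------------------------------------------------------------------


class _Grid:
    """Free-gap bookkeeping per (linac, weekday index)."""

    def __init__(self, config: DepartmentConfig, calendar: list[dt.date]):
        self.config = config
        self.calendar = calendar
        self.gaps: dict[tuple[str, int], list[list[int]]] = {}
        self.nt_events: dict[tuple[str, int], list[tuple[int, int, str]]] = {}

    def init_day(self, linac: LinacConfig, day: int, nt_baseline: dict[str, int]) -> None:
        lo, hi = linac.window(self.calendar[day])
        blocks: list[tuple[int, int, str]] = []
        cursor_blocks = sorted(
            nt_baseline.items(),
            key=lambda kv: lo if NT_ANCHORS.get(kv[0], -1) == -1 else NT_ANCHORS[kv[0]],
        )
        last_end = lo
        for sub, minutes in cursor_blocks:
            anchor = NT_ANCHORS.get(sub, -1)
            start = lo if anchor == -1 else max(anchor, last_end)
            end = min(start + minutes, hi)
            if end > start:
                blocks.append((start, end, sub))
                last_end = end
        blocks.sort()
        key = (linac.linac_id, day)
        self.nt_events[key] = blocks
        gaps: list[list[int]] = []
        cursor = lo
        for s, e, _ in blocks:
            if s > cursor:
                gaps.append([cursor, s])
            cursor = max(cursor, e)
        if cursor < hi:
            gaps.append([cursor, hi])
        self.gaps[key] = gaps

    def max_gap(self, linac_id: str, day: int) -> int:
        return max((e - s for s, e in self.gaps[(linac_id, day)]), default=0)

    def allocate(self, linac_id: str, day: int, minutes: int) -> tuple[int, int]:
        """Carve the earliest fitting gap; returns the slot interval."""
        for gap in self.gaps[(linac_id, day)]:
            s, e = gap
            if e - s >= minutes:
                gap[0] = s + minutes
                if gap[0] == gap[1]:
                    self.gaps[(linac_id, day)].remove(gap)
                return s, s + minutes
        raise RuntimeError(f"no gap of {minutes} min on {linac_id} day {day}")


# --------------------------------------------------------------------------
# Day-0 perturbation
# --------------------------------------------------------------------------


def perturb_day(
    planned_events: Sequence[ScheduleEvent],
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[list[ScheduleEvent], list[dict]]:
    """Turn one day's planned schedule into an observed one.

    Applies, in fixed order per linac: a maintenance/downtime block
    (displacing whatever it overlaps; displaced patient slots are
    cancelled), a patient-QA insertion into the first sufficiently large
    free gap, per-slot treatment cancellations, and no-show flagging
    calibrated so the expected flagged time is ``no_show_rate`` of the
    day's opening hours.  Returns the observed events plus ground-truth
    records of every injected change.
    """
    if not planned_events:
        return [], []
    dates = {ev.date for ev in planned_events}
    if len(dates) != 1:
        raise ValueError("perturb_day expects a single day's events")
    date = dates.pop()
    config = params.department
    records: list[dict] = []
    observed: list[ScheduleEvent] = []

    by_linac: dict[str, list[ScheduleEvent]] = {}
    for ev in planned_events:
        by_linac.setdefault(ev.linac_id, []).append(ev)

    for linac_id in config.linac_ids:
        events = sorted(by_linac.get(linac_id, []), key=lambda e: e.start)
        if not events:
            continue
        lo, hi = config.linac(linac_id).window(date)

        # 1. maintenance / downtime
        if rng.random() < params.maintenance_prob:
            m = min(params.maintenance_minutes, hi - lo)
            latest = (hi - m - lo) // 5
            start = lo + 5 * int(rng.integers(0, max(latest, 0) + 1))
            end = start + m
            kept = []
            for ev in events:
                if ev.start < end and start < ev.end:  # displaced
                    if ev.main_category == TREATMENT:
                        records.append(
                            {
                                "kind": "displaced_treatment",
                                "linac_id": linac_id,
                                "date": date.isoformat(),
                                "minutes": ev.duration,
                                "patient_id": ev.patient_id,
                            }
                        )
                else:
                    kept.append(ev)
            events = kept
            events.append(
                ScheduleEvent(
                    linac_id=linac_id,
                    date=date,
                    start=start,
                    end=end,
                    main_category=NON_TREATMENT,
                    subcategory="Maintenance",
                    status="planned",
                )
            )
            events.sort(key=lambda e: e.start)
            records.append(
                {
                    "kind": "maintenance",
                    "linac_id": linac_id,
                    "date": date.isoformat(),
                    "minutes": m,
                }
            )

        # 2. patient-QA insertion into the first large-enough free gap
        if rng.random() < params.patient_qa_prob:
            q = params.patient_qa_minutes
            cursor = lo
            qa_start = None
            for ev in events:
                if ev.start - cursor >= q:
                    qa_start = cursor
                    break
                cursor = max(cursor, ev.end)
            if qa_start is None and hi - cursor >= q:
                qa_start = cursor
            if qa_start is not None:
                events.append(
                    ScheduleEvent(
                        linac_id=linac_id,
                        date=date,
                        start=qa_start,
                        end=qa_start + q,
                        main_category=NON_TREATMENT,
                        subcategory="PatientQA",
                        status="planned",
                    )
                )
                events.sort(key=lambda e: e.start)
                records.append(
                    {
                        "kind": "patient_qa",
                        "linac_id": linac_id,
                        "date": date.isoformat(),
                        "minutes": q,
                    }
                )

        # 3. per-slot treatment cancellations
        kept = []
        for ev in events:
            if (
                ev.main_category == TREATMENT
                and ev.patient_id is not None
                and rng.random() < params.cancellation_prob
            ):
                records.append(
                    {
                        "kind": "cancellation",
                        "linac_id": linac_id,
                        "date": date.isoformat(),
                        "minutes": ev.duration,
                        "patient_id": ev.patient_id,
                    }
                )
            else:
                kept.append(ev)
        events = kept

        # 4. no-shows: expected flagged minutes = no_show_rate * OH1
        treat = [ev for ev in events if ev.subcategory == "Treatment"]
        treat_minutes = sum(ev.duration for ev in treat)
        if treat_minutes > 0 and params.no_show_rate > 0:
            q_ns = min(1.0, params.no_show_rate * (hi - lo) / treat_minutes)
            flagged_ids = {
                id(ev) for ev in treat if rng.random() < q_ns
            }
        else:
            flagged_ids = set()
        for ev in events:
            flag = id(ev) in flagged_ids
            observed.append(replace(ev, status="observed", no_show=flag))
            if flag:
                records.append(
                    {
                        "kind": "no_show",
                        "linac_id": linac_id,
                        "date": date.isoformat(),
                        "minutes": ev.duration,
                        "patient_id": ev.patient_id,
                    }
                )

    observed.sort(key=lambda e: (e.linac_id, e.start))
    return observed, records


# --------------------------------------------------------------------------
# Full simulation
# --------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """A simulated department: snapshot access plus the ground-truth ledger."""

    params: SimulationParams
    referrals: list[ReferralRecord]
    ledger: dict[str, list[dict]]
    snapshot_dates: list[dt.date]
    _calendar: list[dt.date] = field(repr=False, default_factory=list)
    _first_snapshot_day: int = field(repr=False, default=0)
    _slots: dict[tuple[str, int], list[_Slot]] = field(repr=False, default_factory=dict)
    _grid: _Grid | None = field(repr=False, default=None)
    _observed: dict[dt.date, list[ScheduleEvent]] = field(repr=False, default_factory=dict)

    # -- event materialisation --------------------------------------------

    def _day_events(
        self, linac_id: str, day: int, snapshot_day: int
    ) -> list[ScheduleEvent]:
        date = self._calendar[day]
        h = day - snapshot_day
        events: list[ScheduleEvent] = [
            ScheduleEvent(
                linac_id=linac_id,
                date=date,
                start=s,
                end=e,
                main_category=NON_TREATMENT,
                subcategory=sub,
                status="planned",
            )
            for s, e, sub in self._grid.nt_events[(linac_id, day)]
        ]
        for slot in self._slots.get((linac_id, day), []):
            if slot.kind == "regular":
                if slot.booked_day > snapshot_day:
                    continue  # not yet booked at snapshot time
                sub, pid, sid, frac = "Treatment", slot.patient_id, slot.series_id, slot.fraction_no
            else:  # prebooked placeholder converting to treatment near the date
                if h > slot.convert_lead:
                    sub, pid, sid, frac = "Pre-booked", None, None, None
                else:
                    sub, pid, sid, frac = "Treatment", slot.patient_id, slot.series_id, None
            events.append(
                ScheduleEvent(
                    linac_id=linac_id,
                    date=date,
                    start=slot.start,
                    end=slot.end,
                    main_category=TREATMENT,
                    subcategory=sub,
                    status="planned",
                    patient_id=pid,
                    series_id=sid,
                    fraction_no=frac,
                )
            )
        events.sort(key=lambda e: e.start)
        return events

    def planned_snapshot(self, date: dt.date) -> Snapshot:
        """Morning snapshot: Day 0 plus the forthcoming horizon weekdays."""
        d = self._snapshot_index(date)
        H = self.params.department.horizon_weekdays
        events: list[ScheduleEvent] = []
        for t in range(d, d + H + 1):
            for linac_id in self.params.department.linac_ids:
                events.extend(self._day_events(linac_id, t, d))
        return Snapshot(as_of=date, kind="planned", events=tuple(events))

    def planned_day0_snapshot(self, date: dt.date) -> Snapshot:
        """Planned snapshot restricted to its Day-0 events (cheap)."""
        d = self._snapshot_index(date)
        events: list[ScheduleEvent] = []
        for linac_id in self.params.department.linac_ids:
            events.extend(self._day_events(linac_id, d, d))
        return Snapshot(as_of=date, kind="planned", events=tuple(events))

    def observed_snapshot(self, date: dt.date) -> Snapshot:
        """Evening snapshot of Day 0 as the day actually went."""
        if date not in self._observed:
            raise KeyError(f"no observed snapshot for {date}")
        return Snapshot(as_of=date, kind="observed", events=tuple(self._observed[date]))

    def iter_planned(self) -> Iterator[Snapshot]:
        for date in self.snapshot_dates:
            yield self.planned_snapshot(date)

    def _snapshot_index(self, date: dt.date) -> int:
        try:
            offset = self.snapshot_dates.index(date)
        except ValueError:
            raise KeyError(f"{date} is not a snapshot day") from None
        return self._first_snapshot_day + offset

    # -- persistence -------------------------------------------------------

    def write_archive(self, out_dir: str | Path) -> Path:
        """Write the CSV snapshot archive, ledger and referral table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for date in self.snapshot_dates:
            write_events_csv(
                self.planned_snapshot(date).events, snapshot_path(out, date, "planned")
            )
            write_events_csv(
                self.observed_snapshot(date).events, snapshot_path(out, date, "observed")
            )
        with open(out / "ledger.jsonl", "w", encoding="utf-8") as fh:
            for kind in sorted(self.ledger):
                for rec in self.ledger[kind]:
                    fh.write(json.dumps({"kind": kind, **rec}, sort_keys=True) + "\n")
        with open(out / "referrals.csv", "w", encoding="utf-8") as fh:
            fh.write(
                "patient_id,diagnosis_group,referral_date,preferred_start,"
                "n_fractions,slot_minutes,scheduled\n"
            )
            for r in self.referrals:
                fh.write(
                    f"{r.patient_id},{r.diagnosis_group},{r.referral_date},"
                    f"{r.preferred_start},{r.n_fractions},{r.slot_minutes},"
                    f"{r.scheduled}\n"
                )
        (out / "params.json").write_text(
            self.params.model_dump_json(indent=2) + "\n", encoding="utf-8"
        )
        return out


def run_simulation(
    params: SimulationParams, out_dir: str | Path | None = None
) -> SimulationResult:
    """Run the full simulation; optionally write the archive to disk.

    The same parameters and seed give bit-for-bit identical output.  The
    booking grid extends one horizon before the first snapshot day
    (burn-in, so early snapshots see a mature booking state) and one
    horizon after the last.
    """
    config = params.department
    H = config.horizon_weekdays
    burnin = H + 10
    n_grid = burnin + params.n_days + H  # weekday indices 0 .. n_grid-1

    first_date = _weekdays_before(params.start_date, burnin, config.holidays)
    calendar = weekday_horizon(first_date, n_grid - 1, config.holidays)
    first_snap = burnin
    snapshot_days = list(range(first_snap, first_snap + params.n_days))
    snapshot_dates = [calendar[d] for d in snapshot_days]

    ss = np.random.SeedSequence(params.seed)
    rng_ref, rng_pb, rng_book, rng_perturb = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    ledger: dict[str, list[dict]] = {
        "booking": [],
        "deferral": [],
        "maintenance": [],
        "patient_qa": [],
        "cancellation": [],
        "displaced_treatment": [],
        "no_show": [],
    }

    # --- grid with non-treatment baseline --------------------------------
    grid = _Grid(config, calendar)
    for linac in config.linacs:
        for day in range(n_grid):
            grid.init_day(linac, day, params.nt_baseline)

    # --- pre-booked care-path placeholders --------------------------------
    slots: dict[tuple[str, int], list[_Slot]] = {}
    lo_slot, hi_slot = params.slot_minutes
    cp_counter = 0
    for linac in config.linacs:
        for day in range(n_grid):
            win_lo, win_hi = linac.window(calendar[day])
            target = int(round(params.prebooked_share_at_horizon / 100.0 * (win_hi - win_lo)))
            allocated = 0
            while target - allocated >= lo_slot:
                m = min(int(rng_pb.integers(lo_slot, hi_slot + 1)), target - allocated)
                if grid.max_gap(linac.linac_id, day) < m:
                    break
                s, e = grid.allocate(linac.linac_id, day, m)
                cp_counter += 1
                lead = float(
                    np.clip(
                        rng_pb.logistic(
                            params.prebooked_convert_midpoint,
                            params.prebooked_convert_steepness,
                        ),
                        0.0,
                        H,
                    )
                )
                slots.setdefault((linac.linac_id, day), []).append(
                    _Slot(
                        linac_id=linac.linac_id,
                        day=day,
                        start=s,
                        end=e,
                        kind="prebooked",
                        booked_day=-1,
                        convert_lead=lead,
                        patient_id=f"cp{cp_counter:05d}",
                        series_id=f"cps{cp_counter:05d}",
                    )
                )
                allocated += m

    # --- referral stream and greedy series booking ------------------------
    triples = _draw_referrals(
        params, rng_ref, 0, first_snap + params.n_days, lambda i: calendar[i]
    )
    referrals = [rec for _, _, rec in triples]
    group_ids = config.group_ids
    weights = np.array([len(config.group_members(g)) for g in group_ids], dtype=float)
    weights /= weights.sum()
    series_counter = 0
    for r_day, pref_day, rec in triples:
        series_counter += 1
        gid = str(rng_book.choice(group_ids, p=weights))
        members = list(config.group_members(gid))
        rng_book.shuffle(members)
        k, m = rec.n_fractions, rec.slot_minutes
        s_max = min(r_day + H, n_grid - k)
        placed = None
        for s in range(max(pref_day, 0), s_max + 1):
            for linac_id in members:
                if all(grid.max_gap(linac_id, s + j) >= m for j in range(k)):
                    placed = (linac_id, s)
                    break
            if placed:
                break
        if placed is None:
            ledger["deferral"].append(
                {"patient_id": rec.patient_id, "referral_date": rec.referral_date.isoformat()}
            )
            continue
        linac_id, s = placed
        sid = f"s{series_counter:05d}"
        for j in range(k):
            a, b = grid.allocate(linac_id, s + j, m)
            slots.setdefault((linac_id, s + j), []).append(
                _Slot(
                    linac_id=linac_id,
                    day=s + j,
                    start=a,
                    end=b,
                    kind="regular",
                    booked_day=r_day,
                    convert_lead=-1.0,
                    patient_id=rec.patient_id,
                    series_id=sid,
                    fraction_no=j + 1,
                )
            )
        rec.scheduled = True
        ledger["booking"].append(
            {
                "patient_id": rec.patient_id,
                "series_id": sid,
                "linac_id": linac_id,
                "first_fraction_date": calendar[s].isoformat(),
                "lead_days": s - r_day,
                "n_fractions": k,
                "slot_minutes": m,
            }
        )

    result = SimulationResult(
        params=params,
        referrals=referrals,
        ledger=ledger,
        snapshot_dates=snapshot_dates,
        _calendar=calendar,
        _first_snapshot_day=first_snap,
        _slots=slots,
        _grid=grid,
    )

    # --- observed Day-0 schedules -----------------------------------------
    for d, date in zip(snapshot_days, snapshot_dates):
        planned_day0 = [
            ev
            for linac_id in config.linac_ids
            for ev in result._day_events(linac_id, d, d)
        ]
        observed, recs = perturb_day(planned_day0, params, rng_perturb)
        result._observed[date] = observed
        for rec in recs:
            kind = rec.pop("kind")
            ledger[kind].append(rec)

    if out_dir is not None:
        result.write_archive(out_dir)
    return result


def _weekdays_before(
    date: dt.date, n: int, holidays: Sequence[dt.date] = ()
) -> dt.date:
    """The operating weekday lying n weekdays before ``date``."""
    skip = set(holidays)
    d = date
    remaining = n
    while remaining > 0:
        d -= dt.timedelta(days=1)
        if d.weekday() < 5 and d not in skip:
            remaining -= 1
    return d
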