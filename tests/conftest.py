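"""Shared fixtures: department configs, random-schedule generators and
independent minute-grid oracles used to cross-check interval arithmetic."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lur.config_model import (
    NON_TREATMENT,
    NON_TREATMENT_SUBCATEGORIES,
    TREATMENT,
    DepartmentConfig,
    LinacConfig,
    ScheduleEvent,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

MONDAY = dt.date(2018, 3, 5)
ALL_WEEK = ("Mon", "Tue", "Wed", "Thu", "Fri")


def make_department(
    n_linacs: int = 2, open_time: str = "07:00", close_time: str = "16:15",
    group_id: str = "g1",
) -> DepartmentConfig:
    windows = {k: (open_time, close_time) for k in ALL_WEEK}
    return DepartmentConfig(
        linacs=[
            LinacConfig(
                linac_id=f"L{i}", group_id=group_id, weekday_windows=windows
            )
            for i in range(1, n_linacs + 1)
        ]
    )


@pytest.fixture
def monday() -> dt.date:
    return MONDAY


@pytest.fixture
def department() -> DepartmentConfig:
    """Two identical linacs, 07:00-16:15 (9.25 h/day), one group."""
    return make_department(2)


@pytest.fixture
def study_department() -> DepartmentConfig:
    """The modelled 8-linac park: 4 @ 07:00-16:15 and 4 @ 06:45-16:15."""
    from lur.simulate import default_department

    return default_department()


def random_day_events(
    rng: np.random.Generator,
    linac_id: str,
    date: dt.date,
    day_span: tuple[int, int] = (6 * 60, 17 * 60),
    n_events: int | None = None,
    no_show_prob: float = 0.05,
) -> list[ScheduleEvent]:
    """Random non-overlapping mixed-category events across a day span.

    Events may start before opening or run past closing so that the
    outside-opening (OH2) paths get exercised.
    """
    lo, hi = day_span
    if n_events is None:
        n_events = int(rng.integers(0, 25))
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_events, replace=False))
    events: list[ScheduleEvent] = []
    subs = ("Treatment", "Pre-booked") + NON_TREATMENT_SUBCATEGORIES
    for i in range(n_events):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if s == e:
            continue
        sub = str(rng.choice(subs))
        main = TREATMENT if sub in ("Treatment", "Pre-booked") else NON_TREATMENT
        events.append(
            ScheduleEvent(
                linac_id=linac_id,
                date=date,
                start=s,
                end=e,
                main_category=main,
                subcategory=sub,
                no_show=bool(sub == "Treatment" and rng.random() < no_show_prob),
            )
        )
    return events


# --------------------------------------------------------------------------
# Minute-grid oracles (brute force, independent of the package arithmetic)
# --------------------------------------------------------------------------


def oracle_clip(event: ScheduleEvent, window: tuple[int, int]) -> tuple[int, int]:
    """Count minutes inside/outside a window by enumerating the minute set."""
    minutes = set(range(event.start, event.end))
    inside = len(minutes & set(range(window[0], window[1])))
    return inside, len(minutes) - inside


def oracle_day_minutes(
    events: list[ScheduleEvent], window: tuple[int, int]
) -> dict[str, int]:
    """HT / HNT / OH2 / no-show minutes by minute-by-minute enumeration."""
    win = set(range(window[0], window[1]))
    ht = hnt = oh2 = ns = pb = 0
    for ev in events:
        mins = set(range(ev.start, ev.end))
        oh2 += len(mins - win)
        if ev.main_category == TREATMENT:
            if ev.no_show:
                ns += len(mins)
            else:
                ht += len(mins)
                if ev.subcategory == "Pre-booked":
                    pb += len(mins)
        else:
            hnt += len(mins & win)
    return {"HT": ht, "HNT": hnt, "OH2": oh2, "no_show": ns, "prebooked": pb}


def oracle_overlap(events: list[ScheduleEvent]) -> bool:
    """Pairwise minute-set intersection test for same-linac same-day overlap."""
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            if a.linac_id == b.linac_id and a.date == b.date:
                if set(range(a.start, a.end)) & set(range(b.start, b.end)):
                    return True
    return False


def oracle_signed_rank_exact(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon p by enumerating all sign assignments."""
    d = diffs[diffs != 0]
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    count = 0
    total = 2**n
    for mask in range(total):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total
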