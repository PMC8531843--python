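"""Day-0 planned-vs-observed schedule deviations.

Each operating day yields two snapshots of the same schedule: the planned
one captured in the morning before clinical work starts and the observed
one captured after the day has finished.  This module quantifies how the
day actually differed from its morning plan:

* :func:`diff_day0` — per-linac, per-group and park-level
  :class:`DeltaRecord` objects with rate deltas (observed − planned, in
  percentage points) and per-subcategory minute deltas;
* :func:`count_changes` / :func:`percent_of_days` — how often each rate
  increased or decreased over a period;
* :func:`attribute_nt_increase` — which non-treatment subcategory
  dominates an over-the-day LUR_NT increase above a threshold;
* :func:`deviation_frequency` — share of entity-days whose schedule
  changed at all.

Classification uses exact integer-minute arithmetic: a rate counts as
increased iff the underlying scheduled minutes increased, with no epsilon.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Mapping, Sequence

from .config_model import (
    NON_TREATMENT_SUBCATEGORIES,
    NT_TIE_ORDER,
    TREATMENT_SUBCATEGORIES,
    DepartmentConfig,
    Snapshot,
    SnapshotMismatchError,
    ZeroTotalError,
)
from .metrics import category_minutes

__all__ = [
    "DeltaRecord",
    "diff_day0",
    "count_changes",
    "percent_of_days",
    "attribute_nt_increase",
    "deviation_frequency",
    "nt_attribution_counts",
]

Level = Literal["linac", "group", "park"]
DELTA_METRICS = ("LUR_T", "LUR_NT", "LUR")


@dataclass(frozen=True, slots=True)
class DeltaRecord:
    """Observed-minus-planned change for one entity on one date.

    ``delta_ht_minutes`` / ``delta_hnt_minutes`` are the exact integer
    minute changes behind ``delta_LUR_T`` / ``delta_LUR_NT``; the total
    delta is their sum over the entity's pooled opening minutes, so
    ``delta_LUR == delta_LUR_T + delta_LUR_NT`` pointwise.
    """

    entity_id: str
    level: Level
    date: dt.date
    oh1_minutes: int
    delta_ht_minutes: int
    delta_hnt_minutes: int
    delta_LUR_T: float
    delta_LUR_NT: float
    delta_LUR: float
    category_deltas: Mapping[str, int] = field(default_factory=dict)

    def minute_delta(self, metric: str) -> int:
        if metric == "LUR_T":
            return self.delta_ht_minutes
        if metric == "LUR_NT":
            return self.delta_hnt_minutes
        if metric == "LUR":
            return self.delta_ht_minutes + self.delta_hnt_minutes
        raise ValueError(f"unknown metric {metric!r}")

    def classification(self, metric: str) -> str:
        d = self.minute_delta(metric)
        return "increase" if d > 0 else "decrease" if d < 0 else "none"

    @property
    def deviated(self) -> bool:
        """True when any of the three rates changed (exact minutes)."""
        return any(self.minute_delta(m) != 0 for m in DELTA_METRICS)


def _entity_record(
    entity_id: str,
    level: Level,
    date: dt.date,
    planned: Mapping[str, int],
    observed: Mapping[str, int],
    oh1_minutes: int,
) -> DeltaRecord:
    cats = TREATMENT_SUBCATEGORIES + NON_TREATMENT_SUBCATEGORIES
    deltas = {c: observed[c] - planned[c] for c in cats}
    d_ht = sum(deltas[c] for c in TREATMENT_SUBCATEGORIES)
    d_hnt = sum(deltas[c] for c in NON_TREATMENT_SUBCATEGORIES)
    return DeltaRecord(
        entity_id=entity_id,
        level=level,
        date=date,
        oh1_minutes=oh1_minutes,
        delta_ht_minutes=d_ht,
        delta_hnt_minutes=d_hnt,
        delta_LUR_T=100.0 * d_ht / oh1_minutes,
        delta_LUR_NT=100.0 * d_hnt / oh1_minutes,
        delta_LUR=100.0 * (d_ht + d_hnt) / oh1_minutes,
        category_deltas=deltas,
    )


def diff_day0(
    planned: Snapshot, observed: Snapshot, config: DepartmentConfig
) -> list[DeltaRecord]:
    """Compare the Day-0 schedule of a planned/observed snapshot pair.

    Returns one :class:`DeltaRecord` per linac, per treatment-equivalent
    group and for the whole park.  Group and park deltas are pooled:
    minute deltas summed over members, rates formed over summed opening
    minutes.
    """
    if planned.as_of != observed.as_of:
        raise SnapshotMismatchError(
            f"snapshot dates differ: {planned.as_of} vs {observed.as_of}"
        )
    if planned.kind != "planned" or observed.kind != "observed":
        raise SnapshotMismatchError(
            f"snapshot kinds wrong: {planned.kind}/{observed.kind}"
        )
    date = planned.as_of
    p_day = planned.day0_events()
    o_day = observed.day0_events()

    per_linac_minutes: dict[str, tuple[dict, dict, int]] = {}
    for linac_id in config.linac_ids:
        p_cat = category_minutes(
            [e for e in p_day if e.linac_id == linac_id], config, linac_id, date
        )
        o_cat = category_minutes(
            [e for e in o_day if e.linac_id == linac_id], config, linac_id, date
        )
        lo, hi = config.linac(linac_id).window(date)
        per_linac_minutes[linac_id] = (p_cat, o_cat, hi - lo)

    def _pooled(members: Sequence[str]) -> tuple[dict, dict, int]:
        cats = TREATMENT_SUBCATEGORIES + NON_TREATMENT_SUBCATEGORIES
        p_sum = {c: 0 for c in cats}
        o_sum = {c: 0 for c in cats}
        oh1 = 0
        for m in members:
            p_cat, o_cat, oh = per_linac_minutes[m]
            oh1 += oh
            for c in cats:
                p_sum[c] += p_cat[c]
                o_sum[c] += o_cat[c]
        return p_sum, o_sum, oh1

    records = [
        _entity_record(lid, "linac", date, *per_linac_minutes[lid][:2],
                       per_linac_minutes[lid][2])
        for lid in config.linac_ids
    ]
    for gid in config.group_ids:
        records.append(
            _entity_record(gid, "group", date, *_pooled(config.group_members(gid)))
        )
    records.append(_entity_record("park", "park", date, *_pooled(config.linac_ids)))
    return records


def count_changes(
    deltas: Sequence[DeltaRecord], metric: str
) -> tuple[int, int, int]:
    """``(n_increase, n_decrease, n_none)`` for one metric; counts partition."""
    levels = {r.level for r in deltas}
    if len(levels) > 1:
        raise ValueError(f"records mix levels: {sorted(levels)}")
    n_inc = sum(1 for r in deltas if r.classification(metric) == "increase")
    n_dec = sum(1 for r in deltas if r.classification(metric) == "decrease")
    return n_inc, n_dec, len(deltas) - n_inc - n_dec


def percent_of_days(count: int, total: int) -> int:
    """Integer percent, rounded half away from zero (e.g. 745/3390 → 22)."""
    if total <= 0:
        raise ZeroTotalError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return int(Fraction(100 * count, total) + Fraction(1, 2))


def attribute_nt_increase(
    record: DeltaRecord, threshold_pp: float
) -> str | None:
    """Dominant non-treatment subcategory behind an LUR_NT increase.

    Returns ``None`` unless the record's LUR_NT delta exceeds
    ``threshold_pp`` percentage points; otherwise the non-treatment
    subcategory with the largest positive minute delta, ties broken by a
    fixed order (Maintenance first, then PatientQA, ...).
    """
    if record.level != "linac":
        raise ValueError("attribution is defined at linac level")
    # exact threshold test on minutes: delta_pp > t  <=>  100*d > t*oh1
    if 100 * record.delta_hnt_minutes <= threshold_pp * record.oh1_minutes:
        return None
    best: str | None = None
    best_minutes = 0
    for sub in NT_TIE_ORDER:
        d = record.category_deltas.get(sub, 0)
        if d > best_minutes:
            best, best_minutes = sub, d
    return best


def deviation_frequency(deltas: Sequence[DeltaRecord], level: Level) -> int:
    """Percent of entity-days at a level whose schedule changed at all.

    At linac level the unit is a linac-day, at group level a group-day,
    at park level a calendar day; a unit deviates when any of the three
    rates has a nonzero exact minute delta.
    """
    at_level = [r for r in deltas if r.level == level]
    if not at_level:
        raise ZeroTotalError(f"no records at level {level!r}")
    n_dev = sum(1 for r in at_level if r.deviated)
    return percent_of_days(n_dev, len(at_level))


def nt_attribution_counts(
    deltas: Sequence[DeltaRecord], thresholds: Sequence[float] = (0.0, 2.0, 5.0)
) -> dict[float, dict[str, object]]:
    """Attribution tables for LUR_NT increases at several thresholds.

    For each threshold: counts per dominant subcategory plus two
    occurrence rates — per all linac-days and per attributed (deviating
    above threshold) linac-days, since either denominator is a reasonable
    reading of "rate of occurrence".
    """
    linac_records = [r for r in deltas if r.level == "linac"]
    out: dict[float, dict[str, object]] = {}
    for t in thresholds:
        counts: dict[str, int] = {}
        for rec in linac_records:
            sub = attribute_nt_increase(rec, t)
            if sub is not None:
                counts[sub] = counts.get(sub, 0) + 1
        n_attr = sum(counts.values())
        n_all = len(linac_records)
        out[t] = {
            "counts": dict(sorted(counts.items(), key=lambda kv: -kv[1])),
            "n_attributed": n_attr,
            "n_linac_days": n_all,
            "rate_per_all_days": {
                s: percent_of_days(c, n_all) for s, c in counts.items()
            },
            "rate_per_attributed_days": {
                s: percent_of_days(c, n_attr) for s, c in counts.items()
            } if n_attr else {},
        }
    return out
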