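"""Prospective utilization over the 0–100 weekday planning horizon.

Every morning snapshot contains not just today's plan (Day 0) but the
plan for the forthcoming horizon of weekdays.  Indexing each future date
by its distance *h* in weekdays from the snapshot day and pooling over
many snapshots yields, for any metric and entity, a mean ± SD curve of
scheduled utilization as a function of how far ahead one looks.

On such a curve "the date approaches" as *h* decreases, so the rate of
booking build-up per day is −dP/dh of a polynomial fit P(h); the planning
horizon with the steepest build-up is located via the real roots of the
second derivative d²P/dh² (candidates) inside the range, falling back to
the range endpoints.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from numpy.polynomial import polynomial as npoly

from .config_model import (
    DepartmentConfig,
    EmptyArchiveError,
    RankDeficiencyError,
    Snapshot,
    iter_snapshots,
    weekday_horizon,
)
from .metrics import METRIC_NAMES, entity_day_metrics

__all__ = [
    "HorizonSeries",
    "PolyFitResult",
    "build_horizon_series",
    "fit_polynomial",
    "steepest_increase_day",
    "max_metric_day",
    "transition_day",
]


@dataclass(frozen=True)
class HorizonSeries:
    """Mean/SD of one metric as a function of planning horizon h.

    ``h`` runs 0..H (weekdays ahead of the snapshot date); ``n[h]`` counts
    the snapshots contributing to point ``h``.  SD uses the n−1
    denominator and is reported as 0 where n == 1.
    """

    metric: str
    entity_id: str
    h: np.ndarray  # int, shape (H+1,)
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.h) == len(self.mean) == len(self.sd) == len(self.n)):
            raise ValueError("h/mean/sd/n must have equal length")


@dataclass(frozen=True)
class PolyFitResult:
    """Least-squares polynomial fit of mean(h); coefficients ascending in h."""

    degree: int
    coefficients: tuple[float, ...]
    rmse: float
    h_range: tuple[int, int]


def build_horizon_series(
    archive: str | Path | Iterable[Snapshot],
    config: DepartmentConfig,
    metric: str = "LUR_T",
    entity_id: str = "park",
    horizon: int | None = None,
    method: Literal["pooled", "mean_of_linacs"] = "pooled",
) -> HorizonSeries:
    """Pool planned snapshots into a mean ± SD curve over the horizon.

    ``archive`` is a snapshot directory or any iterable of planned
    :class:`~lur.config_model.Snapshot` objects.  For each snapshot taken
    on date *d*, the metric evaluated on the schedule of the date lying
    *h* weekdays after *d* contributes one observation to point *h*.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    H = horizon if horizon is not None else config.horizon_weekdays
    snapshots: Iterable[Snapshot]
    if isinstance(archive, (str, Path)):
        snapshots = iter_snapshots(archive, kind="planned")
    else:
        snapshots = archive
    members = set(config.entity_members(entity_id))

    sums = np.zeros(H + 1)
    sq_sums = np.zeros(H + 1)
    counts = np.zeros(H + 1, dtype=int)
    n_snapshots = 0
    for snap in snapshots:
        n_snapshots += 1
        dates = weekday_horizon(snap.as_of, H, config.holidays)
        by_date: dict[dt.date, list] = {d: [] for d in dates}
        for ev in snap.events:
            if ev.linac_id in members and ev.date in by_date:
                by_date[ev.date].append(ev)
        for h, date in enumerate(dates):
            value = entity_day_metrics(
                by_date[date], config, entity_id, date, method=method
            ).value(metric)
            sums[h] += value
            sq_sums[h] += value * value
            counts[h] += 1
    if n_snapshots == 0:
        raise EmptyArchiveError("no planned snapshots in archive")

    mean = sums / counts
    with np.errstate(invalid="ignore"):
        var = np.where(
            counts > 1, (sq_sums - counts * mean**2) / np.maximum(counts - 1, 1), 0.0
        )
    sd = np.sqrt(np.maximum(var, 0.0))
    return HorizonSeries(
        metric=metric,
        entity_id=entity_id,
        h=np.arange(H + 1),
        mean=mean,
        sd=sd,
        n=counts,
    )


def fit_polynomial(series: HorizonSeries, degree: int = 4) -> PolyFitResult:
    """Least-squares polynomial fit of the mean curve against h."""
    if len(series.h) < degree + 1:
        raise RankDeficiencyError(
            f"{len(series.h)} points cannot determine degree {degree}"
        )
    coeffs = npoly.polyfit(series.h.astype(float), series.mean, degree)
    fitted = npoly.polyval(series.h.astype(float), coeffs)
    rmse = float(np.sqrt(np.mean((fitted - series.mean) ** 2)))
    return PolyFitResult(
        degree=degree,
        coefficients=tuple(float(c) for c in coeffs),
        rmse=rmse,
        h_range=(int(series.h[0]), int(series.h[-1])),
    )


def steepest_increase_day(
    fit: PolyFitResult, h_range: tuple[int, int] | None = None
) -> tuple[int, bool]:
    """Horizon day where booked utilization grows fastest per day.

    Utilization rises as the target date approaches (h decreasing), so
    the build-up rate is −P′(h); its interior stationary points are the
    real roots of P″(h).  Candidate days are the roots inside the range
    at which −P′ has a local maximum (P‴ > 0); when no such root exists
    the range endpoints serve as fallback.  The integer candidate
    maximizing −P′ wins, ties to the smallest h.  Returns
    ``(h_star, interior)`` with ``interior=False`` when the result sits
    on a range endpoint.
    """
    if fit.degree < 2:
        raise ValueError("steepest-increase analysis needs degree >= 2")
    lo, hi = h_range if h_range is not None else fit.h_range
    coeffs = np.asarray(fit.coefficients)
    d1 = npoly.polyder(coeffs)
    d2 = npoly.polyder(coeffs, 2)
    d3 = npoly.polyder(coeffs, 3)
    candidates: set[int] = set()
    if len(d2) > 1:
        for r in npoly.polyroots(d2):
            if abs(r.imag) < 1e-9 and lo <= r.real <= hi:
                # keep only local maxima of -P' (concave stationary points)
                if fit.degree == 2 or npoly.polyval(r.real, d3) > 0:
                    candidates.add(int(np.clip(round(r.real), lo, hi)))
    if not candidates:
        candidates = {lo, hi}
    best_h, best_val = None, -np.inf
    for h in sorted(candidates):
        val = -npoly.polyval(float(h), d1)
        if val > best_val + 1e-12:
            best_h, best_val = h, val
    assert best_h is not None
    return best_h, best_h not in (lo, hi)


def max_metric_day(series: HorizonSeries) -> int:
    """Horizon day with maximal mean; ties broken toward the smallest h."""
    if len(series.h) == 0:
        raise ValueError("empty series")
    return int(series.h[int(np.argmax(series.mean))])


def transition_day(series: HorizonSeries, level_pp: float) -> int:
    """Horizon day at which a rising share falls to ``level_pp``.

    Intended for the pre-booked share, which is ~0 near Day 0 (all
    placeholders have converted to scheduled treatments) and grows with
    h.  Scanning h upward from 0, returns the largest h whose mean is
    still ≤ ``level_pp`` before the first exceedance; if the series never
    exceeds the level, returns the last horizon day with a warning.
    """
    means = series.mean
    above = np.nonzero(means > level_pp)[0]
    if above.size == 0:
        warnings.warn(
            f"series never exceeds {level_pp} pp; returning horizon end",
            stacklevel=2,
        )
        return int(series.h[-1])
    first = int(above[0])
    return int(series.h[first - 1]) if first > 0 else int(series.h[0])
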