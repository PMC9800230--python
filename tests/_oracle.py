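"""Brute-force patient-day-grid oracle.

Materialises one boolean (or unit count) per patient-day with naive loops
and re-derives chronic status, discontinuation and episode segmentation
from the grid.  Deliberately independent of ppicohort's implementation:
everything here is day-by-day enumeration.
"""

from __future__ import annotations

import datetime as dt
import math

ONE_DAY = dt.timedelta(days=1)


def _day_range(start: dt.date, end: dt.date):
    d = start
    while d <= end:
        yield d
        d += ONE_DAY


def units_dispensed_per_day(fills: list[tuple[dt.date, int]]) -> dict[dt.date, int]:
    grid: dict[dt.date, int] = {}
    for t, u in fills:
        grid[t] = grid.get(t, 0) + u
    return grid


def covered_days(fills: list[tuple[dt.date, int]]) -> set[dt.date]:
    covered = set()
    for t, u in fills:
        for d in _day_range(t, t + dt.timedelta(days=u - 1)):
            covered.add(d)
    return covered


def oracle_chronic(fills, year: int, threshold: float = 0.80) -> bool:
    grid = units_dispensed_per_day(fills)
    window = list(_day_range(dt.date(year - 1, 10, 1), dt.date(year - 1, 12, 31)))
    total = sum(grid.get(d, 0) for d in window)
    return total >= math.ceil(threshold * len(window))


def oracle_user_on(fills, day: dt.date) -> bool:
    return day in covered_days(fills)


def oracle_incident(fills, year: int, threshold: float = 0.80) -> bool:
    return (oracle_chronic(fills, year, threshold)
            and not oracle_user_on(fills, dt.date(year - 1, 1, 1)))


def oracle_discontinued(fills, year: int) -> bool:
    grid = units_dispensed_per_day(fills)
    return not any(grid.get(d, 0) > 0
                   for d in _day_range(dt.date(year, 11, 1), dt.date(year, 12, 31)))


def oracle_episodes(fills, gap_days: int = 61) -> list[tuple[dt.date, dt.date, int]]:
    """Maximal covered runs after merging uncovered runs < gap_days."""
    if not fills:
        return []
    covered = covered_days(fills)
    grid = units_dispensed_per_day(fills)
    first, last = min(covered), max(covered)
    episodes = []
    start = None
    uncovered_run = 0
    prev_covered_day = None
    for d in _day_range(first, last):
        if d in covered:
            if start is None:
                start = d
            elif uncovered_run >= gap_days:
                episodes.append((start, prev_covered_day))
                start = d
            uncovered_run = 0
            prev_covered_day = d
        else:
            uncovered_run += 1
    episodes.append((start, prev_covered_day))
    out = []
    for s, e in episodes:
        n = sum(u for t, u in grid.items() if s <= t <= e)
        out.append((s, e, n))
    return out
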