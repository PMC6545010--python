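"""ISO-week calendar windows and weekly aggregation of AG episodes.

Surveillance seasons follow the ISO-8601 week calendar: the *winter*
season of year N runs from week 36 of N through week 15 of N+1 (32 or
33 weeks, depending on whether year N has 52 or 53 ISO weeks); the
*summer* period covers weeks 16-35 of N+1 (always 20 weeks).  Episodes
are counted by the ISO week of their index dispense date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

WeekKey = Tuple[int, int]

AGE_GROUPS = ["0-4", "5-14", "15-64", "65+"]


def iso_weeks_in_year(year: int) -> int:
    # Dec 28 always lies in the last ISO week of its year.
    return dt.date(year, 12, 28).isocalendar()[1]


def age_group(age_years: int) -> str:
    if age_years < 0:
        raise ValueError("age must be non-negative")
    if age_years <= 4:
        return "0-4"
    if age_years <= 14:
        return "5-14"
    if age_years <= 64:
        return "15-64"
    return "65+"


@dataclass(frozen=True)
class SeasonWindow:
    label: str
    kind: str  # winter | summer
    weeks: Tuple[WeekKey, ...]

    @property
    def start_date(self) -> dt.date:
        y, w = self.weeks[0]
        return dt.date.fromisocalendar(y, w, 1)

    @property
    def end_date(self) -> dt.date:
        y, w = self.weeks[-1]
        return dt.date.fromisocalendar(y, w, 7)

    def __len__(self) -> int:
        return len(self.weeks)

    def __contains__(self, week: WeekKey) -> bool:
        return week in self.weeks

    def index_of(self, week: WeekKey) -> int:
        return self.weeks.index(week)


def winter_window(start_year: int) -> SeasonWindow:
    """Winter season: weeks 36..last of ``start_year``, then 1..15 of the next."""
    if start_year < 1900:
        raise ValueError("start_year must be >= 1900")
    last = iso_weeks_in_year(start_year)
    weeks = [(start_year, w) for w in range(36, last + 1)]
    weeks += [(start_year + 1, w) for w in range(1, 16)]
    label = f"{start_year}/{(start_year + 1) % 100:02d}-winter"
    return SeasonWindow(label=label, kind="winter", weeks=tuple(weeks))


def summer_window(start_year: int) -> SeasonWindow:
    """Summer period of season ``start_year``: weeks 16-35 of the next year."""
    if start_year < 1900:
        raise ValueError("start_year must be >= 1900")
    weeks = tuple((start_year + 1, w) for w in range(16, 36))
    label = f"{start_year}/{(start_year + 1) % 100:02d}-summer"
    return SeasonWindow(label=label, kind="summer", weeks=weeks)


def season_of_week(year: int, week: int) -> str:
    """Season label owning an ISO week (winter weeks 36+/1-15, summer 16-35)."""
    if week >= 36:
        return winter_window(year).label
    if week <= 15:
        return winter_window(year - 1).label
    return summer_window(year - 1).label


def season_of_date(date: dt.date) -> str:
    y, w, _ = date.isocalendar()
    return season_of_week(y, w)


@dataclass
class WeeklySeries:
    """Episode counts per window week for one stratum."""

    stratum: str
    window: SeasonWindow
    values: List[float]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.window.weeks):
            raise ValueError("values must align with window weeks")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "iso_year": [w[0] for w in self.window.weeks],
                "iso_week": [w[1] for w in self.window.weeks],
                "value": self.values,
            }
        )


def aggregate_weekly(
    episodes,
    window: SeasonWindow,
    stratifier: Optional[str] = None,
) -> Tuple[Dict[str, WeeklySeries], int]:
    """Count episode index dates per window week, per stratum.

    ``stratifier`` is ``None`` (one "all" series), ``"age"`` (the four
    age groups) or ``"region"``.  Returns ``(series_by_stratum,
    n_ignored)`` where ``n_ignored`` counts episodes dated outside the
    window.
    """
    if stratifier not in (None, "age", "region"):
        raise ValueError("stratifier must be None, 'age' or 'region'")

    if stratifier is None:
        strata = ["all"]
    elif stratifier == "age":
        strata = list(AGE_GROUPS)
    else:
        strata = sorted({ep.region_code for ep in episodes})

    counts = {s: [0.0] * len(window.weeks) for s in strata}
    ignored = 0
    for ep in episodes:
        y, w, _ = ep.index_date.isocalendar()
        if (y, w) not in window:
            ignored += 1
            continue
        if stratifier is None:
            s = "all"
        elif stratifier == "age":
            s = age_group(ep.age_at_index)
        else:
            s = ep.region_code
        counts[s][window.index_of((y, w))] += 1

    return {s: WeeklySeries(s, window, counts[s]) for s in strata}, ignored


def sentinel_to_series(
    records, window: SeasonWindow, stratum: str = "all"
) -> WeeklySeries:
    """Align sentinel records of one stratum onto a season window.

    Missing weeks raise: the sentinel comparator must cover the window.
    """
    table = {(r.iso_year, r.iso_week): r.estimated_cases for r in records if r.stratum == stratum}
    values = []
    for wk in window.weeks:
        if wk not in table:
            raise ValueError(f"sentinel series {stratum!r} missing week {wk}")
        values.append(float(table[wk]))
    return WeeklySeries(stratum, window, values)
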