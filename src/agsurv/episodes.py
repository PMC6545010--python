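"""Collapse AG-classified dispenses into episodes; exclude heavy users.

Two consecutive AG dispenses of the same patient more than 15 days apart
are independent episodes; otherwise the later one is a treatment
renewal of the same episode.  By default the gap is measured from the
previous dispense in the chain (rolling anchor); measuring from the
episode's index date is available as ``anchor="index"``.

Patients with more than 3 detected episodes in one season are likely
chronic users of AG-class drugs rather than AG cases; all their episodes
in that season are removed from the weekly indicator.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .classify import AlgorithmParams, ClassificationResult
from .weeks import season_of_date


@dataclass
class AGEpisode:
    patient_id: str
    index_date: dt.date
    renewal_dates: List[dt.date]
    season_label: str
    age_at_index: int
    region_code: str

    @property
    def n_renewals(self) -> int:
        return len(self.renewal_dates)


@dataclass(frozen=True)
class PatientSeasonSummary:
    patient_id: str
    season_label: str
    n_episodes: int
    excluded: bool


@dataclass
class _Dispense:
    """The minimal view of one AG-classified dispense the builder needs."""

    patient_id: str
    dispense_date: dt.date
    age_years: int
    region_code: str


def dispenses_from_results(results: Sequence[ClassificationResult]) -> List[_Dispense]:
    """Extract the AG-positive dispenses from classification results."""
    return [
        _Dispense(
            patient_id=r.event.patient_id,
            dispense_date=r.event.dispense_date,
            age_years=r.event.age_years,
            region_code=r.event.region_code,
        )
        for r in results
        if r.is_ag
    ]


def build_episodes(
    dispenses: Sequence[_Dispense],
    params: AlgorithmParams = AlgorithmParams(),
) -> List[AGEpisode]:
    """Chain one patient's date-sorted AG dispenses into episodes.

    A dispense within ``renewal_window_days`` of the chain's anchor
    (previous dispense for ``anchor="rolling"``, episode index date for
    ``anchor="index"``) joins the current episode as a renewal; a larger
    gap starts a new episode.  Input must be one patient's dispenses in
    non-decreasing date order.
    """
    if not dispenses:
        return []
    pid = dispenses[0].patient_id
    dates = [d.dispense_date for d in dispenses]
    if any(d.patient_id != pid for d in dispenses):
        raise ValueError("build_episodes expects a single patient's dispenses")
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("dispenses must be sorted by dispense_date")

    episodes: List[AGEpisode] = []
    current: AGEpisode = None  # type: ignore[assignment]
    anchor_date: dt.date = None  # type: ignore[assignment]
    for d in dispenses:
        if current is not None and (d.dispense_date - anchor_date).days <= params.renewal_window_days:
            current.renewal_dates.append(d.dispense_date)
            if params.anchor == "rolling":
                anchor_date = d.dispense_date
        else:
            current = AGEpisode(
                patient_id=pid,
                index_date=d.dispense_date,
                renewal_dates=[],
                season_label=season_of_date(d.dispense_date),
                age_at_index=d.age_years,
                region_code=d.region_code,
            )
            episodes.append(current)
            anchor_date = d.dispense_date
    return episodes


def build_all_episodes(
    dispenses: Sequence[_Dispense],
    params: AlgorithmParams = AlgorithmParams(),
) -> List[AGEpisode]:
    """Group by patient, sort by date, chain each patient independently."""
    by_patient: Dict[str, List[_Dispense]] = {}
    for d in dispenses:
        by_patient.setdefault(d.patient_id, []).append(d)
    episodes: List[AGEpisode] = []
    for pid in sorted(by_patient):
        per = sorted(by_patient[pid], key=lambda d: d.dispense_date)
        episodes.extend(build_episodes(per, params))
    return episodes


def apply_heavy_user_exclusion(
    episodes: Sequence[AGEpisode],
    params: AlgorithmParams = AlgorithmParams(),
) -> Tuple[List[AGEpisode], List[PatientSeasonSummary]]:
    """Drop every episode of a patient-season with too many episodes.

    The threshold is strict: exactly ``max_episodes_per_season`` episodes
    are kept; one more removes the whole patient-season.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for ep in episodes:
        key = (ep.patient_id, ep.season_label)
        counts[key] = counts.get(key, 0) + 1

    summaries = [
        PatientSeasonSummary(pid, season, n, n > params.max_episodes_per_season)
        for (pid, season), n in sorted(counts.items())
    ]
    excluded = {
        (s.patient_id, s.season_label) for s in summaries if s.excluded
    }
    kept = [ep for ep in episodes if (ep.patient_id, ep.season_label) not in excluded]
    return kept, summaries


def episodes_to_frame(episodes: Sequence[AGEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": ep.patient_id,
                "season_label": ep.season_label,
                "index_date": ep.index_date.isoformat(),
                "n_renewals": ep.n_renewals,
                "age_at_index": ep.age_at_index,
                "region_code": ep.region_code,
            }
            for ep in episodes
        ],
        columns=[
            "patient_id",
            "season_label",
            "index_date",
            "n_renewals",
            "age_at_index",
            "region_code",
        ],
    )


def summaries_to_frame(summaries: Sequence[PatientSeasonSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "season_label": s.season_label,
                "n_episodes": s.n_episodes,
                "excluded": s.excluded,
            }
            for s in summaries
        ],
        columns=["patient_id", "season_label", "n_episodes", "excluded"],
    )
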