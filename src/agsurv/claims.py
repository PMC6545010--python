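"""Dispensing-line and sentinel-series I/O.

A *dispense line* is one drug product on one pharmacy visit.  A *dispense
event* — the unit the discrimination algorithm classifies — is the basket
of all lines sharing (patient, prescription date, dispense date,
prescriber).  Sentinel records carry the weekly estimated case counts of
the comparison surveillance system, stratified by age group or region.

Rows with malformed dates or a dispense date before the prescription date
are not fatal: they are collected in a rejects table with the originating
line number and a reason code, mirroring how claims extracts are cleaned
in practice.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import pandas as pd

DISPENSE_HEADER = [
    "patient_id",
    "birth_year",
    "sex",
    "dispense_date",
    "prescription_date",
    "prescriber_specialty",
    "region_code",
    "drug_code",
    "n_boxes",
]

SENTINEL_HEADER = ["iso_year", "iso_week", "stratum", "estimated_cases"]


class FormatError(ValueError):
    """Raised when an input file does not match its expected dialect."""


@dataclass(frozen=True)
class DispenseLine:
    patient_id: str
    birth_year: Optional[int]
    sex: str
    dispense_date: dt.date
    prescription_date: Optional[dt.date]
    prescriber_specialty: str
    region_code: str
    drug_code: str
    n_boxes: int


@dataclass
class DispenseEvent:
    """All lines of one patient/prescription-date/dispense-date/prescriber."""

    patient_id: str
    dispense_date: dt.date
    prescription_date: Optional[dt.date]
    prescriber_specialty: str
    region_code: str
    age_years: Optional[int]
    lines: List[DispenseLine] = field(default_factory=list)


@dataclass(frozen=True)
class SentinelRecord:
    iso_year: int
    iso_week: int
    stratum: str
    estimated_cases: float


def _parse_date(raw: str) -> Optional[dt.date]:
    raw = (raw or "").strip()
    if not raw:
        return None
    return dt.date.fromisoformat(raw)


def read_dispense_lines(
    path: Union[str, Path],
) -> Tuple[List[DispenseLine], pd.DataFrame]:
    """Read a dispense-line CSV.

    Returns ``(lines, rejects)`` where ``rejects`` is a DataFrame with
    columns ``line_number`` (1-based, header = line 1) and ``reason``.
    Missing prescription dates are accepted (eligibility filters them
    later); malformed dates and negative dispense lags are rejected row
    by row.
    """
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = [c for c in DISPENSE_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    lines: List[DispenseLine] = []
    rejects: List[Tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            disp = _parse_date(row.dispense_date)
            presc = _parse_date(row.prescription_date)
        except ValueError:
            rejects.append((idx, "malformed-date"))
            continue
        if disp is None:
            rejects.append((idx, "missing-dispense-date"))
            continue
        if presc is not None and disp < presc:
            rejects.append((idx, "dispense-before-prescription"))
            continue
        try:
            n_boxes = int(row.n_boxes)
        except ValueError:
            rejects.append((idx, "malformed-n-boxes"))
            continue
        if n_boxes < 1:
            rejects.append((idx, "nonpositive-n-boxes"))
            continue
        birth = row.birth_year.strip()
        lines.append(
            DispenseLine(
                patient_id=row.patient_id,
                birth_year=int(birth) if birth else None,
                sex=row.sex if row.sex in ("M", "F") else "unknown",
                dispense_date=disp,
                prescription_date=presc,
                prescriber_specialty=(
                    row.prescriber_specialty
                    if row.prescriber_specialty in ("GP", "other")
                    else "unknown"
                ),
                region_code=row.region_code,
                drug_code=row.drug_code,
                n_boxes=n_boxes,
            )
        )
    rejects_df = pd.DataFrame(rejects, columns=["line_number", "reason"])
    return lines, rejects_df


def assemble_events(lines: List[DispenseLine]) -> List[DispenseEvent]:
    """Group lines into dispense events.

    Key: (patient_id, dispense_date, prescription_date, prescriber).
    Age is dispense-year minus birth-year (the records store only the
    year of birth).  Order-independent: a shuffled input yields the same
    events; events come back sorted by key.
    """
    buckets: dict = {}
    for ln in lines:
        key = (ln.patient_id, ln.dispense_date, ln.prescription_date, ln.prescriber_specialty)
        buckets.setdefault(key, []).append(ln)
    events = []
    for (pid, disp, presc, spec) in sorted(
        buckets, key=lambda k: (k[0], k[1], k[2] or dt.date.min, k[3])
    ):
        grp = buckets[(pid, disp, presc, spec)]
        birth = grp[0].birth_year
        events.append(
            DispenseEvent(
                patient_id=pid,
                dispense_date=disp,
                prescription_date=presc,
                prescriber_specialty=spec,
                region_code=grp[0].region_code,
                age_years=(disp.year - birth) if birth is not None else None,
                lines=grp,
            )
        )
    return events


def read_sentinel_series(path: Union[str, Path]) -> List[SentinelRecord]:
    """Read a sentinel weekly-incidence CSV; duplicates and bad weeks are fatal."""
    df = pd.read_csv(Path(path))
    missing = [c for c in SENTINEL_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        year, week = int(row.iso_year), int(row.iso_week)
        if not 1 <= week <= 53:
            raise FormatError(f"{path}: iso_week {week} outside 1-53")
        if week == 53 and dt.date(year, 12, 28).isocalendar()[1] != 53:
            raise FormatError(f"{path}: {year} has no ISO week 53")
        key = (year, week, str(row.stratum))
        if key in seen:
            raise FormatError(f"{path}: duplicate record {key}")
        seen.add(key)
        cases = float(row.estimated_cases)
        if cases < 0:
            raise FormatError(f"{path}: negative estimated_cases at {key}")
        records.append(SentinelRecord(year, week, str(row.stratum), cases))
    return records


def write_dispense_lines(lines: List[DispenseLine], path: Union[str, Path]) -> None:
    rows = [
        {
            "patient_id": ln.patient_id,
            "birth_year": "" if ln.birth_year is None else ln.birth_year,
            "sex": ln.sex,
            "dispense_date": ln.dispense_date.isoformat(),
            "prescription_date": (
                "" if ln.prescription_date is None else ln.prescription_date.isoformat()
            ),
            "prescriber_specialty": ln.prescriber_specialty,
            "region_code": ln.region_code,
            "drug_code": ln.drug_code,
            "n_boxes": ln.n_boxes,
        }
        for ln in lines
    ]
    pd.DataFrame(rows, columns=DISPENSE_HEADER).to_csv(Path(path), index=False)


def write_sentinel_series(records: List[SentinelRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "iso_year": r.iso_year,
            "iso_week": r.iso_week,
            "stratum": r.stratum,
            "estimated_cases": r.estimated_cases,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SENTINEL_HEADER).to_csv(Path(path), index=False)
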