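import random

import pytest

from agsurv.claims import (
    FormatError,
    assemble_events,
    read_dispense_lines,
    read_sentinel_series,
    write_dispense_lines,
)

HEADER = (
    "patient_id,birth_year,sex,dispense_date,prescription_date,"
    "prescriber_specialty,region_code,drug_code,n_boxes\n"
)


def write(tmp_path, rows, name="lines.csv"):
    p = tmp_path / name
    p.write_text(HEADER + "".join(r + "\n" for r in rows), encoding="utf-8")
    return p


def test_well_formed_rows_parse(tmp_path):
    rows = [
        f"P1,1980,F,2016-01-0{i},2016-01-01,GP,R01,U-ORS,1" for i in range(1, 6)
    ]
    lines, rejects = read_dispense_lines(write(tmp_path, rows))
    assert len(lines) == 5 and rejects.empty


def test_malformed_date_rejected_with_line_number(tmp_path):
    rows = [
        "P1,1980,F,2016-01-02,2016-01-01,GP,R01,U-ORS,1",
        "P1,1980,F,2015-13-40,2015-12-01,GP,R01,U-ORS,1",
        "P1,1980,F,2016-01-03,2016-01-02,GP,R01,U-AEO,1",
        "P1,1980,F,2016-01-04,2016-01-03,GP,R01,U-PRO,2",
        "P1,1980,F,2016-01-05,2016-01-04,GP,R01,U-ABS,1",
    ]
    lines, rejects = read_dispense_lines(write(tmp_path, rows))
    assert len(lines) == 4
    assert rejects.line_number.tolist() == [3]  # header is line 1
    assert rejects.reason.tolist() == ["malformed-date"]


def test_missing_prescription_date_accepted(tmp_path):
    rows = ["P1,1980,F,2016-01-02,,GP,R01,U-ORS,1"]
    lines, rejects = read_dispense_lines(write(tmp_path, rows))
    assert len(lines) == 1 and lines[0].prescription_date is None and rejects.empty


def test_dispense_before_prescription_rejected(tmp_path):
    rows = ["P1,1980,F,2016-01-02,2016-01-05,GP,R01,U-ORS,1"]
    lines, rejects = read_dispense_lines(write(tmp_path, rows))
    assert not lines
    assert rejects.reason.tolist() == ["dispense-before-prescription"]


def test_missing_column_is_fatal(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("patient_id,birth_year\nP1,1980\n", encoding="utf-8")
    with pytest.raises(FormatError, match="missing columns"):
        read_dispense_lines(p)


def test_events_group_by_patient_dates_prescriber(tmp_path):
    rows = [
        "P1,1980,F,2016-01-02,2016-01-01,GP,R01,U-ORS,1",
        "P1,1980,F,2016-01-02,2016-01-01,GP,R01,U-AEO,1",
        "P1,1980,F,2016-01-02,2016-01-01,GP,R01,P-ASP,1",
        "P1,1980,F,2016-01-03,2016-01-01,GP,R01,U-ORS,1",
    ]
    lines, _ = read_dispense_lines(write(tmp_path, rows))
    events = assemble_events(lines)
    assert [len(e.lines) for e in events] == [3, 1]  # dispense date splits events


def test_age_is_year_difference(tmp_path):
    # year-of-birth precision: age = dispense year - birth year
    rows = ["P1,2012,F,2016-01-10,2016-01-10,GP,R01,U-ORS,1"]
    lines, _ = read_dispense_lines(write(tmp_path, rows))
    events = assemble_events(lines)
    assert events[0].age_years == 4


def test_grouping_is_order_independent_and_conserves_lines(tmp_path):
    rows = [
        f"P{p},19{70 + p},M,2016-01-{d:02d},2016-01-{d:02d},GP,R0{p},U-ORS,1"
        for p in range(1, 4)
        for d in range(1, 5)
    ] * 2  # duplicated lines still count toward conservation
    lines, _ = read_dispense_lines(write(tmp_path, rows))
    shuffled = lines[:]
    random.Random(7).shuffle(shuffled)
    ev_a, ev_b = assemble_events(lines), assemble_events(shuffled)
    key = lambda e: (e.patient_id, e.dispense_date, e.prescription_date)
    assert [key(e) for e in ev_a] == [key(e) for e in ev_b]
    assert sum(len(e.lines) for e in ev_a) == len(lines)


def test_roundtrip_write_read(tmp_path):
    rows = ["P1,1980,F,2016-01-02,2016-01-01,GP,R01,U-ORS,1"]
    lines, _ = read_dispense_lines(write(tmp_path, rows))
    out = tmp_path / "again.csv"
    write_dispense_lines(lines, out)
    lines2, _ = read_dispense_lines(out)
    assert lines == lines2


SENT_HEADER = "iso_year,iso_week,stratum,estimated_cases\n"


def test_sentinel_reads_records(tmp_path):
    body = "".join(f"2015,{w},all,{100 + w}\n" for w in range(1, 33))
    p = tmp_path / "sent.csv"
    p.write_text(SENT_HEADER + body, encoding="utf-8")
    records = read_sentinel_series(p)
    assert len(records) == 32
    assert records[0].stratum == "all"


def test_sentinel_duplicate_is_fatal(tmp_path):
    p = tmp_path / "sent.csv"
    p.write_text(SENT_HEADER + "2015,2,all,100\n2015,2,all,101\n", encoding="utf-8")
    with pytest.raises(FormatError, match="duplicate"):
        read_sentinel_series(p)


def test_sentinel_week_53_only_in_53_week_years(tmp_path):
    ok = tmp_path / "ok.csv"
    ok.write_text(SENT_HEADER + "2015,53,all,10\n", encoding="utf-8")
    assert read_sentinel_series(ok)[0].iso_week == 53  # 2015 has 53 ISO weeks
    bad = tmp_path / "bad.csv"
    bad.write_text(SENT_HEADER + "2016,53,all,10\n", encoding="utf-8")
    with pytest.raises(FormatError, match="53"):
        read_sentinel_series(bad)
    out_of_range = tmp_path / "oor.csv"
    out_of_range.write_text(SENT_HEADER + "2016,54,all,10\n", encoding="utf-8")
    with pytest.raises(FormatError):
        read_sentinel_series(out_of_range)
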