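import datetime as dt

import pytest

from agsurv.catalog import toy_catalog
from agsurv.claims import DispenseEvent, DispenseLine


@pytest.fixture(scope="session")
def catalog():
    return toy_catalog()


def make_event(
    basket,
    age=30,
    lag=0,
    prescriber="GP",
    dispense_date=dt.date(2017, 1, 9),
    prescription_date="auto",
    patient_id="P1",
    region="R01",
):
    """Build a dispense event from (drug_code, n_boxes) pairs.

    ``prescription_date="auto"`` derives it from the dispense date and
    the requested lag; pass ``None`` for a missing prescription date.
    """
    if prescription_date == "auto":
        prescription_date = dispense_date - dt.timedelta(days=lag)
    birth_year = dispense_date.year - age if age is not None else None
    lines = [
        DispenseLine(
            patient_id=patient_id,
            birth_year=birth_year,
            sex="F",
            dispense_date=dispense_date,
            prescription_date=prescription_date,
            prescriber_specialty=prescriber,
            region_code=region,
            drug_code=code,
            n_boxes=boxes,
        )
        for code, boxes in basket
    ]
    return DispenseEvent(
        patient_id=patient_id,
        dispense_date=dispense_date,
        prescription_date=prescription_date,
        prescriber_specialty=prescriber,
        region_code=region,
        age_years=age,
        lines=lines,
    )


@pytest.fixture
def event_factory():
    return make_event
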