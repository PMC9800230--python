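"""Shared fixture builders: tiny hand-written claims datasets."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from ppicohort.claims_io import ClaimsDataset


def make_patients(rows):
    """rows: (patient_id, birth_date, sex, death_date, in_region)."""
    return pd.DataFrame(
        rows, columns=["patient_id", "birth_date", "sex", "death_date", "in_region"])


def make_dispensings(rows):
    """rows: (patient_id, dispense_date, units) or full 8-tuples."""
    full = []
    for r in rows:
        if len(r) == 3:
            pid, date, units = r
            full.append((pid, date, "omeprazole", 20.0, units, "oral",
                         f"{pid}-RX1", "general_practitioner"))
        else:
            full.append(tuple(r))
    return pd.DataFrame(full, columns=[
        "patient_id", "dispense_date", "inn", "dosage_mg", "units_dispensed",
        "route", "prescription_id", "prescriber_specialty"])


def make_dataset(patients, dispensings, years=(2016, 2017, 2018),
                 population=1000) -> ClaimsDataset:
    drug_ref = pd.DataFrame({
        "inn": ["omeprazole", "omeprazole", "esomeprazole"],
        "dosage_mg": [10.0, 20.0, 20.0],
        "ddd_mg": [20.0, 20.0, 30.0],
    })
    denominators = pd.DataFrame({"year": list(years),
                                 "count": [population] * len(years)})
    return ClaimsDataset(patients, dispensings, drug_ref, denominators)


@pytest.fixture
def adult_patient():
    return make_patients([
        ("A", dt.date(1950, 6, 1), "female", None, True),
    ])


@pytest.fixture
def chronic_2017_records():
    """One patient dispensed 74 units inside Oct-Dec 2016 (chronic on
    2017-01-01) plus year-round 2017 coverage ending mid-October."""
    return make_dispensings([
        ("A", dt.date(2016, 10, 5), 30),
        ("A", dt.date(2016, 11, 6), 30),
        ("A", dt.date(2016, 12, 8), 14),
        ("A", dt.date(2017, 1, 10), 30),
        ("A", dt.date(2017, 10, 15), 30),
    ])
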