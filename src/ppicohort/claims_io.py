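"""Data model and flat-file I/O for longitudinal pharmacy-dispensing claims.

The analysis consumes four tables, all plain CSV with ISO-8601 dates:

``patients.csv``
    ``patient_id,birth_date,sex,death_date,in_region`` — one row per insured
    person.  ``death_date`` may be empty; ``in_region`` is ``true``/``false``.
``dispensings.csv``
    ``patient_id,dispense_date,inn,dosage_mg,units_dispensed,route,
    prescription_id,prescriber_specialty`` — one row per reimbursed
    dispensing event.  One dispensed unit is one oral dose (one day of
    treatment).
``drug_reference.csv``
    ``inn,dosage_mg,ddd_mg`` — the defined daily dose (assumed average adult
    maintenance dose, mg/day) for every dispensed product.
``population.csv``
    ``year,count`` — general-population denominators for rate estimation.

Reading validates types, value domains and referential integrity and raises
:class:`ValidationError` naming the offending file, row and field.  Patients
flagged outside the study region are dropped at read time (with a logged
count), mirroring a region-restricted claims extraction.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PPI_INNS",
    "SEXES",
    "ROUTES",
    "SPECIALTIES",
    "ClaimsDataset",
    "ExclusionLog",
    "ValidationError",
    "age_at",
    "apply_exclusions",
    "read_dataset",
    "write_dataset",
]

#: The five oral proton-pump-inhibitor molecules tracked by the analysis.
PPI_INNS = frozenset(
    {"esomeprazole", "lansoprazole", "omeprazole", "pantoprazole", "rabeprazole"}
)
SEXES = frozenset({"male", "female"})
ROUTES = frozenset({"oral", "parenteral"})
SPECIALTIES = frozenset({"general_practitioner", "specialist", "institution"})

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "death_date", "in_region"]
DISPENSING_COLUMNS = [
    "patient_id",
    "dispense_date",
    "inn",
    "dosage_mg",
    "units_dispensed",
    "route",
    "prescription_id",
    "prescriber_specialty",
]
DRUG_REFERENCE_COLUMNS = ["inn", "dosage_mg", "ddd_mg"]
POPULATION_COLUMNS = ["year", "count"]


class ValidationError(ValueError):
    """A file failed schema, domain or referential-integrity validation."""

    def __init__(self, file: str, message: str, row: int | None = None,
                 fieldname: str | None = None):
        self.file = file
        self.row = row
        self.fieldname = fieldname
        where = file
        if row is not None:
            where += f", row {row}"
        if fieldname is not None:
            where += f", field '{fieldname}'"
        super().__init__(f"{where}: {message}")


@dataclass
class ClaimsDataset:
    """Validated in-memory claims dataset (all members are DataFrames).

    ``drug_reference`` is indexable through :meth:`ddd_mg`; ``denominators``
    through :meth:`population`.
    """

    patients: pd.DataFrame
    dispensings: pd.DataFrame
    drug_reference: pd.DataFrame
    denominators: pd.DataFrame

    def ddd_mg(self, inn: str, dosage_mg: float) -> float:
        ref = self.drug_reference
        hit = ref[(ref["inn"] == inn) & (ref["dosage_mg"] == dosage_mg)]
        if hit.empty:
            raise KeyError(f"no DDD entry for {inn} {dosage_mg:g} mg")
        return float(hit["ddd_mg"].iloc[0])

    def population(self, year: int) -> int:
        den = self.denominators
        hit = den[den["year"] == year]
        if hit.empty:
            raise KeyError(f"no population denominator for year {year}")
        return int(hit["count"].iloc[0])


@dataclass
class ExclusionLog:
    """Per-rule tallies of patients/rows removed by the study's exclusions."""

    out_of_region: int = 0
    under_18: int = 0
    parenteral_only: int = 0
    parenteral_rows_dropped: int = 0
    excluded_patient_ids: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, int]:
        return {
            "out_of_region": self.out_of_region,
            "under_18": self.under_18,
            "parenteral_only": self.parenteral_only,
            "parenteral_rows_dropped": self.parenteral_rows_dropped,
        }


def age_at(birth_date: dt.date, anchor: dt.date) -> int:
    """Completed years of age at ``anchor``."""
    years = anchor.year - birth_date.year
    if (anchor.month, anchor.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# reading / validation

def _parse_dates(df: pd.DataFrame, col: str, file: str, allow_na: bool = False) -> None:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(file, f"unparseable date '{df[col].iloc[row]}'",
                              row=row, fieldname=col)
    if not allow_na and parsed.isna().any():
        row = int(parsed.isna().idxmax())
        raise ValidationError(file, "missing date", row=row, fieldname=col)
    dates = parsed.dt.date
    df[col] = dates.where(pd.notna(dates), None)


def _require_columns(df: pd.DataFrame, cols: list[str], file: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(file, f"missing column(s) {missing}")


def _check_domain(df: pd.DataFrame, col: str, allowed: frozenset, file: str) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(
            file, f"value '{df[col].iloc[row]}' not in {sorted(allowed)}",
            row=row, fieldname=col)


def read_patients(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read and validate patients.csv; drop out-of-region patients.

    Returns the retained patients and the number of out-of-region rows
    dropped.
    """
    file = str(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, PATIENT_COLUMNS, file)
    if df["patient_id"].duplicated().any():
        row = int(df["patient_id"].duplicated().idxmax())
        raise ValidationError(file, "duplicate patient_id", row=row,
                              fieldname="patient_id")
    _parse_dates(df, "birth_date", file)
    _parse_dates(df, "death_date", file, allow_na=True)
    _check_domain(df, "sex", SEXES, file)
    if df["in_region"].dtype != bool:
        mapped = df["in_region"].astype(str).str.lower().map(
            {"true": True, "false": False})
        if mapped.isna().any():
            row = int(mapped.isna().idxmax())
            raise ValidationError(file, "in_region must be true/false", row=row,
                                  fieldname="in_region")
        df["in_region"] = mapped
    df["in_region"] = df["in_region"].astype(bool)
    bad = df["death_date"].notna() & (df["death_date"] < df["birth_date"])
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(file, "death_date precedes birth_date", row=row,
                              fieldname="death_date")
    n_out = int((~df["in_region"]).sum())
    df = df[df["in_region"]].reset_index(drop=True)
    return df[PATIENT_COLUMNS], n_out


def read_dispensings(path: str | Path, patients: pd.DataFrame) -> pd.DataFrame:
    file = str(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "prescription_id": str})
    _require_columns(df, DISPENSING_COLUMNS, file)
    _parse_dates(df, "dispense_date", file)
    _check_domain(df, "inn", PPI_INNS, file)
    _check_domain(df, "route", ROUTES, file)
    _check_domain(df, "prescriber_specialty", SPECIALTIES, file)
    if (df["units_dispensed"] < 1).any():
        row = int((df["units_dispensed"] < 1).idxmax())
        raise ValidationError(file, "units_dispensed < 1", row=row,
                              fieldname="units_dispensed")
    if (df["dosage_mg"] <= 0).any():
        row = int((df["dosage_mg"] <= 0).idxmax())
        raise ValidationError(file, "dosage_mg <= 0", row=row, fieldname="dosage_mg")
    orphan = ~df["patient_id"].isin(set(patients["patient_id"]))
    if orphan.any():
        row = int(orphan.idxmax())
        raise ValidationError(
            file, f"patient_id '{df['patient_id'].iloc[row]}' not in patients table",
            row=row, fieldname="patient_id")
    df["units_dispensed"] = df["units_dispensed"].astype(int)
    df["dosage_mg"] = df["dosage_mg"].astype(float)
    return df[DISPENSING_COLUMNS]


def read_drug_reference(path: str | Path, dispensings: pd.DataFrame) -> pd.DataFrame:
    file = str(path)
    df = pd.read_csv(path)
    _require_columns(df, DRUG_REFERENCE_COLUMNS, file)
    if (df["ddd_mg"] <= 0).any():
        row = int((df["ddd_mg"] <= 0).idxmax())
        raise ValidationError(file, "ddd_mg <= 0", row=row, fieldname="ddd_mg")
    df["dosage_mg"] = df["dosage_mg"].astype(float)
    have = set(zip(df["inn"], df["dosage_mg"]))
    used = set(zip(dispensings["inn"], dispensings["dosage_mg"].astype(float)))
    missing = used - have
    if missing:
        inn, dose = sorted(missing)[0]
        raise ValidationError(
            file, f"no DDD entry for dispensed product {inn} {dose:g} mg",
            fieldname="ddd_mg")
    return df[DRUG_REFERENCE_COLUMNS]


def read_population(path: str | Path) -> pd.DataFrame:
    file = str(path)
    df = pd.read_csv(path)
    _require_columns(df, POPULATION_COLUMNS, file)
    if (df["count"] <= 0).any():
        row = int((df["count"] <= 0).idxmax())
        raise ValidationError(file, "population count <= 0", row=row,
                              fieldname="count")
    df["year"] = df["year"].astype(int)
    df["count"] = df["count"].astype(int)
    return df[POPULATION_COLUMNS]


def read_dataset(directory: str | Path) -> tuple[ClaimsDataset, int]:
    """Read a claims dataset directory; returns (dataset, n_out_of_region).

    Expects ``patients.csv``, ``dispensings.csv``, ``drug_reference.csv`` and
    ``population.csv`` under ``directory``.
    """
    directory = Path(directory)
    patients, n_out = read_patients(directory / "patients.csv")
    dispensings = read_dispensings(directory / "dispensings.csv", patients)
    drug_reference = read_drug_reference(directory / "drug_reference.csv", dispensings)
    denominators = read_population(directory / "population.csv")
    return ClaimsDataset(patients, dispensings, drug_reference, denominators), n_out


# ---------------------------------------------------------------------------
# writing

def _date_str(d) -> str:
    return "" if d is None or pd.isna(d) else d.isoformat()


def write_dataset(dataset: ClaimsDataset, directory: str | Path) -> None:
    """Write the four CSV tables with ISO dates and stable row order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pat = dataset.patients.copy()
    pat["birth_date"] = pat["birth_date"].map(_date_str)
    pat["death_date"] = pat["death_date"].map(_date_str)
    pat["in_region"] = pat["in_region"].map(lambda v: "true" if v else "false")
    pat.to_csv(directory / "patients.csv", index=False)
    disp = dataset.dispensings.copy()
    disp["dispense_date"] = disp["dispense_date"].map(_date_str)
    disp.to_csv(directory / "dispensings.csv", index=False)
    dataset.drug_reference.to_csv(directory / "drug_reference.csv", index=False)
    dataset.denominators.to_csv(directory / "population.csv", index=False)


# ---------------------------------------------------------------------------
# study exclusions

def apply_exclusions(
    patients: pd.DataFrame,
    dispensings: pd.DataFrame,
    anchor_year: int,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Apply the study's inclusion/exclusion rules.

    Removes patients younger than 18 completed years on January 1 of
    ``anchor_year`` and patients whose every dispensing is parenteral;
    parenteral rows of retained (mixed-route) patients are dropped from the
    returned dispensings so they never enter dose counting.  Inputs are not
    mutated; the returned log tallies each rule.  The operation is
    idempotent.
    """
    log = ExclusionLog()
    anchor = dt.date(anchor_year, 1, 1)
    ages = patients["birth_date"].map(lambda b: age_at(b, anchor))
    minors = set(patients.loc[ages < 18, "patient_id"])

    by_route = dispensings.groupby("patient_id")["route"].agg(
        lambda r: (r == "parenteral").all())
    parenteral_only = set(by_route[by_route].index) - minors

    for pid in minors:
        log.excluded_patient_ids[pid] = "under_18"
    for pid in parenteral_only:
        log.excluded_patient_ids[pid] = "parenteral_only"
    log.under_18 = len(minors)
    log.parenteral_only = len(parenteral_only)

    excluded = minors | parenteral_only
    patients_out = patients[~patients["patient_id"].isin(excluded)].reset_index(drop=True)
    disp = dispensings[~dispensings["patient_id"].isin(excluded)]
    parenteral_rows = disp["route"] == "parenteral"
    log.parenteral_rows_dropped = int(parenteral_rows.sum())
    dispensings_out = disp[~parenteral_rows].reset_index(drop=True)
    return patients_out, dispensings_out, log
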