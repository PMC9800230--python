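"""Seeded synthetic dispensing-claims generator with planted ground truth.

Emulates a multi-year regional pharmacy-claims extract for chronic
proton-pump-inhibitor users: an adult age/sex structure, annual onset of
chronic use, imperfect refill adherence (boxes dispensed at stochastic
intervals), an annual discontinuation hazard with possible resumption after
a two-month-plus gap, deaths, a molecule-and-strength dispensing mix, and a
GP-dominated prescriber mix.  Every generated label (chronic patient-year,
discontinuation, treatment episode) is planted by construction and recorded
as ground truth, so the classification pipeline can be validated against
known answers and planted rates can be recovered statistically.

Determinism: one PRNG stream is derived per patient from ``(seed, patient
index)``, so outputs are byte-identical across runs and adding patients
never perturbs existing ones.

The cadence model — 30-unit boxes refilled at intervals of roughly
``box_units / adherence``, with a top-up dispensing whenever a planted
chronic quarter would otherwise fall short of 74 units — is an assumption;
real refill cadence is not described by any published table (see
docs/methods.md).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import claims_io
from .exposure import CHRONIC_WINDOW_DAYS, DEFAULT_COVERAGE_THRESHOLD, dose_threshold

__all__ = [
    "DEFAULT_DDD_MG",
    "DEFAULT_DRUG_MIX",
    "DEFAULT_PRESCRIBER_MIX",
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_dispensings",
    "generate_population",
    "write_synthetic_dataset",
]

ONE_DAY = dt.timedelta(days=1)

#: Molecule+strength dispensing-event mix (regional 2017 shares, normalised).
_RAW_MIX = {
    "esomeprazole 10 mg": 0.12,
    "esomeprazole 20 mg": 22.31,
    "esomeprazole 40 mg": 17.88,
    "lansoprazole 15 mg": 6.75,
    "lansoprazole 30 mg": 5.84,
    "omeprazole 10 mg": 3.66,
    "omeprazole 20 mg": 14.73,
    "pantoprazole 20 mg": 12.02,
    "pantoprazole 40 mg": 7.57,
    "rabeprazole 10 mg": 3.74,
    "rabeprazole 20 mg": 5.39,
}
_MIX_TOTAL = sum(_RAW_MIX.values())
DEFAULT_DRUG_MIX = {k: v / _MIX_TOTAL for k, v in _RAW_MIX.items()}

DEFAULT_PRESCRIBER_MIX = {
    "general_practitioner": 0.88,
    "institution": 0.105,
    "specialist": 0.015,
}

#: Example defined-daily-dose table (mg/day) for the five molecules; a
#: plausible reference fixture, not asserted as any agency's official values.
DEFAULT_DDD_MG = {
    "esomeprazole": 30.0,
    "lansoprazole": 30.0,
    "omeprazole": 20.0,
    "pantoprazole": 40.0,
    "rabeprazole": 20.0,
}


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic claims process.

    Rate defaults mirror the magnitudes of the emulated regional study:
    ~1.5% of the adult population newly chronic per year, a 12.5% annual
    discontinuation hazard among chronic users, deaths rare on the scale of
    the published before-cutoff tallies, a 54.4% female share, and a
    GP-dominated prescriber mix.
    """

    n_patients: int = Field(default=10_000, gt=0)
    study_start: dt.date = dt.date(2016, 10, 1)
    study_end: dt.date = dt.date(2020, 12, 31)
    annual_new_chronic_probability: float = Field(default=0.015, ge=0, le=1)
    annual_discontinuation_probability: float = Field(default=0.125, ge=0, le=1)
    adherence_mean: float = Field(default=0.92, gt=0, lt=1)
    adherence_sd: float = Field(default=0.05, gt=0)
    resumption_probability: float = Field(default=0.30, ge=0, le=1)
    annual_death_probability: float = Field(default=0.001, ge=0, le=1)
    age_mean: float = Field(default=68.0, gt=18)
    age_sd: float = Field(default=15.0, gt=0)
    female_fraction: float = Field(default=0.544, ge=0, le=1)
    drug_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_DRUG_MIX))
    prescriber_mix: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PRESCRIBER_MIX))
    parenteral_fraction: float = Field(default=0.0, ge=0, le=1)
    box_units: int = Field(default=30, ge=14, le=90)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        for name in ("drug_mix", "prescriber_mix"):
            mix = getattr(self, name)
            if not mix:
                raise ValueError(f"{name} must be non-empty")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has a negative probability")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        bad = set(self.prescriber_mix) - claims_io.SPECIALTIES
        if bad:
            raise ValueError(f"prescriber_mix has unknown specialties {sorted(bad)}")
        return self

    @field_validator("drug_mix")
    @classmethod
    def _check_products(cls, mix):
        for key in mix:
            inn, _ = _parse_product(key)
            if inn not in claims_io.PPI_INNS:
                raise ValueError(f"drug_mix: unknown molecule in '{key}'")
        return mix

    @property
    def classification_years(self) -> list[int]:
        """January 1 anchors fully covered by the study window."""
        return list(range(self.study_start.year + 1, self.study_end.year + 1))


def _parse_product(key: str) -> tuple[str, float]:
    parts = key.split()
    if len(parts) < 2:
        raise ValueError(f"drug_mix key '{key}' is not 'inn dose mg'")
    return parts[0], float(parts[1])


@dataclass
class GroundTruth:
    """Planted labels: one status row per chronic patient-year and one row
    per true treatment episode.  ``true_discontinued`` implies
    ``true_chronic``; episode intervals are disjoint and ordered."""

    status: pd.DataFrame     # patient_id, year, true_chronic, true_incident, true_discontinued
    episodes: pd.DataFrame   # patient_id, start_date, end_date, n_doses


def _patient_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index, stream]))


# ---------------------------------------------------------------------------
# population


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the synthetic insured population.

    Ages are normal (``age_mean``, ``age_sd``) truncated to >= 18 completed
    years at the first January 1 anchor; sex is Bernoulli
    (``female_fraction``); each calendar year carries an independent death
    probability.  Fully determined by ``config.seed``.
    """
    anchor = dt.date(config.study_start.year + 1, 1, 1)
    rows = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i, 0)
        age = float(rng.normal(config.age_mean, config.age_sd))
        tries = 0
        while age < 18.05 and tries < 1000:
            age = float(rng.normal(config.age_mean, config.age_sd))
            tries += 1
        age = max(age, 18.05)
        birth = anchor - dt.timedelta(days=round(age * 365.25))
        sex = "female" if rng.random() < config.female_fraction else "male"
        death = None
        for year in range(config.study_start.year, config.study_end.year + 1):
            if rng.random() < config.annual_death_probability:
                jan1 = dt.date(year, 1, 1)
                n_days = (dt.date(year, 12, 31) - jan1).days + 1
                death = jan1 + dt.timedelta(days=int(rng.integers(0, n_days)))
                break
        rows.append({
            "patient_id": f"P{i:06d}",
            "birth_date": birth,
            "sex": sex,
            "death_date": death,
            "in_region": True,
        })
    return pd.DataFrame(rows, columns=claims_io.PATIENT_COLUMNS)


# ---------------------------------------------------------------------------
# dispensings


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = min(sd * sd, mean * (1 - mean) * 0.95)
    k = mean * (1 - mean) / var - 1
    return mean * k, (1 - mean) * k


def _plan_periods(rng, config: GeneratorConfig, death: dt.date | None):
    """Plan treatment periods [(first fill, last-fill intent, stop year)].

    Within each calendar year: an untreated patient may start (onset or
    resumption); a patient in treatment on Jan 1 may discontinue that year,
    with the last fill no later than mid-October so the closing two months
    are refill-free.  Planned starts begin Feb 1 or later, keeping every
    resumption gap comfortably above the two-month episode cut.
    """
    periods = []
    in_treatment = False
    ever_stopped = False
    cur_start = None
    stop_years = []
    for year in range(config.study_start.year, config.study_end.year + 1):
        if death is not None and year > death.year:
            break
        if not in_treatment:
            p_start = (config.resumption_probability if ever_stopped
                       else config.annual_new_chronic_probability)
            if rng.random() < p_start:
                if year == config.study_start.year:
                    start = config.study_start + dt.timedelta(int(rng.integers(0, 15)))
                else:
                    start = dt.date(year, 2, 1) + dt.timedelta(int(rng.integers(0, 210)))
                in_treatment = True
                cur_start = start
        else:
            if rng.random() < config.annual_discontinuation_probability:
                stop = dt.date(year, 3, 1) + dt.timedelta(int(rng.integers(0, 225)))
                periods.append((cur_start, stop))
                stop_years.append(year)
                in_treatment = False
                ever_stopped = True
    if in_treatment:
        periods.append((cur_start, config.study_end))
        stop_years.append(None)
    if death is not None:
        trimmed = []
        for (s, e), sy in zip(periods, stop_years):
            if s >= death:
                continue
            trimmed.append(((s, min(e, death)), sy))
        periods = [p for p, _ in trimmed]
        stop_years = [sy for _, sy in trimmed]
    return periods, stop_years


def _materialise_period(rng, config: GeneratorConfig, start: dt.date,
                        last_fill: dt.date, coverage: float,
                        death: dt.date | None) -> list[tuple[dt.date, int]]:
    """Dispense boxes from ``start`` while fills stay within ``last_fill``."""
    fills = []
    t = start
    box = config.box_units
    while t <= last_fill:
        if death is not None and t > death:
            break
        fills.append((t, box))
        step = max(box, round(box / coverage)) + int(rng.integers(0, 5))
        t = t + dt.timedelta(days=step)
    return fills


def _top_up(fills: list[tuple[dt.date, int]], year: int, need: int) -> None:
    """Guarantee >= ``need`` units dated inside Oct 1 – Dec 31 of ``year``."""
    w_start, w_end = dt.date(year, 10, 1), dt.date(year, 12, 31)
    in_window = [(t, u) for t, u in fills if w_start <= t <= w_end]
    have = sum(u for _, u in in_window)
    if have >= need:
        return
    last = max((t for t, _ in in_window), default=dt.date(year, 11, 14))
    fills.append((min(last + ONE_DAY, w_end), need - have))
    fills.sort()


def generate_dispensings(
    patients: pd.DataFrame,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the dispensing stream and its planted ground truth.

    Guarantees, per patient: every planted chronic patient-year carries at
    least 74 units dated inside the prior October–December quarter; every
    planted discontinuation year has no fill in November–December; every
    resumption is preceded by >= 61 uncovered days; no fill falls outside
    the study window or after death.  Ground-truth labels are recomputed
    from the emitted fills with direct window arithmetic, so they are exact
    properties of the data, not merely intents.
    """
    if len(patients) != config.n_patients:
        raise ValueError(
            f"patients table has {len(patients)} rows, config.n_patients is "
            f"{config.n_patients}; was it generated with this config?")
    need = dose_threshold(DEFAULT_COVERAGE_THRESHOLD, CHRONIC_WINDOW_DAYS)
    products = list(config.drug_mix)
    product_p = np.array([config.drug_mix[k] for k in products])
    specialties = list(config.prescriber_mix)
    specialty_p = np.array([config.prescriber_mix[k] for k in specialties])
    a, b = _beta_params(config.adherence_mean, config.adherence_sd)

    disp_rows = []
    status_rows = []
    episode_rows = []
    class_years = config.classification_years

    for i, patient in enumerate(patients.itertuples(index=False)):
        rng = _patient_rng(config.seed, i, 1)
        pid = patient.patient_id
        death = patient.death_date
        if death is not None and pd.isna(death):
            death = None
        coverage = float(np.clip(rng.beta(a, b), 0.80, 0.99))
        inn, dosage = _parse_product(products[int(rng.choice(len(products), p=product_p))])

        periods, _ = _plan_periods(rng, config, death)
        patient_fills: list[list[tuple[dt.date, int]]] = []
        for start, last_fill in periods:
            fills = _materialise_period(rng, config, start, last_fill, coverage, death)
            if not fills:
                continue
            # chronic-quarter guarantee for every year the period spans past Dec 31
            for year in range(start.year, config.study_end.year):
                end_of_year = dt.date(year, 12, 31)
                if last_fill >= end_of_year and (death is None or death > end_of_year):
                    _top_up(fills, year, need)
            patient_fills.append(fills)

        # prescriptions: a new prescription every third fill of a period
        rx_counter = 0
        for fills in patient_fills:
            for j, (t, u) in enumerate(fills):
                if j % 3 == 0:
                    rx_counter += 1
                    rx_id = f"{pid}-RX{rx_counter:03d}"
                    specialty = specialties[int(rng.choice(len(specialties), p=specialty_p))]
                disp_rows.append({
                    "patient_id": pid,
                    "dispense_date": t,
                    "inn": inn,
                    "dosage_mg": dosage,
                    "units_dispensed": int(u),
                    "route": "oral",
                    "prescription_id": rx_id,
                    "prescriber_specialty": specialty,
                })

        # optional extra parenteral rows (exclusion-rule fixtures)
        if config.parenteral_fraction > 0 and rng.random() < config.parenteral_fraction:
            day_span = (config.study_end - config.study_start).days + 1
            t = config.study_start + dt.timedelta(int(rng.integers(0, day_span)))
            if death is None or t <= death:
                rx_counter += 1
                disp_rows.append({
                    "patient_id": pid,
                    "dispense_date": t,
                    "inn": inn,
                    "dosage_mg": dosage,
                    "units_dispensed": 1,
                    "route": "parenteral",
                    "prescription_id": f"{pid}-RX{rx_counter:03d}",
                    "prescriber_specialty": "institution",
                })

        # ---- ground truth, recomputed from the emitted fills ----
        all_fills = sorted(f for fills in patient_fills for f in fills)
        for year in class_years:
            jan1 = dt.date(year, 1, 1)
            if death is not None and death < jan1:
                continue
            w_start, w_end = dt.date(year - 1, 10, 1), dt.date(year - 1, 12, 31)
            units = sum(u for t, u in all_fills if w_start <= t <= w_end)
            if units < need:
                continue
            prev_jan1 = dt.date(year - 1, 1, 1)
            prior_user = any(t <= prev_jan1 <= t + dt.timedelta(days=u - 1)
                             for t, u in all_fills)
            nov1 = dt.date(year, 11, 1)
            dec31 = dt.date(year, 12, 31)
            refilled = any(nov1 <= t <= dec31 for t, u in all_fills)
            status_rows.append({
                "patient_id": pid,
                "year": year,
                "true_chronic": True,
                "true_incident": not prior_user,
                "true_discontinued": not refilled,
            })
        for fills in patient_fills:
            episode_rows.append({
                "patient_id": pid,
                "start_date": fills[0][0],
                "end_date": max(t + dt.timedelta(days=u - 1) for t, u in fills),
                "n_doses": int(sum(u for _, u in fills)),
            })

    dispensings = pd.DataFrame(disp_rows, columns=claims_io.DISPENSING_COLUMNS)
    dispensings = dispensings.sort_values(
        ["patient_id", "dispense_date", "prescription_id"]).reset_index(drop=True)
    truth = GroundTruth(
        status=pd.DataFrame(
            status_rows,
            columns=["patient_id", "year", "true_chronic", "true_incident",
                     "true_discontinued"]),
        episodes=pd.DataFrame(
            episode_rows,
            columns=["patient_id", "start_date", "end_date", "n_doses"]),
    )
    return dispensings, truth


# ---------------------------------------------------------------------------
# whole-dataset convenience


def _reference_tables(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for key in sorted(config.drug_mix):
        inn, dosage = _parse_product(key)
        rows.append({"inn": inn, "dosage_mg": dosage, "ddd_mg": DEFAULT_DDD_MG[inn]})
    drug_reference = pd.DataFrame(rows, columns=claims_io.DRUG_REFERENCE_COLUMNS)
    denominators = pd.DataFrame({
        "year": list(range(config.study_start.year, config.study_end.year + 1)),
        "count": config.n_patients,
    })
    return drug_reference, denominators


def generate_dataset(config: GeneratorConfig) -> tuple[claims_io.ClaimsDataset, GroundTruth]:
    """Generate a complete validated dataset (patients, dispensings, DDD
    reference, denominators) plus ground truth.  The synthetic panel is its
    own general population, so the denominator equals ``n_patients``."""
    patients = generate_population(config)
    dispensings, truth = generate_dispensings(patients, config)
    drug_reference, denominators = _reference_tables(config)
    return claims_io.ClaimsDataset(patients, dispensings, drug_reference,
                                   denominators), truth


def write_synthetic_dataset(config: GeneratorConfig, directory: str | Path
                            ) -> tuple[claims_io.ClaimsDataset, GroundTruth]:
    """Generate and write the dataset, ground truth and generating config."""
    directory = Path(directory)
    dataset, truth = generate_dataset(config)
    claims_io.write_dataset(dataset, directory)
    truth_status = truth.status.copy()
    truth_status.to_csv(directory / "ground_truth.csv", index=False)
    eps = truth.episodes.copy()
    eps["start_date"] = eps["start_date"].map(lambda d: d.isoformat())
    eps["end_date"] = eps["end_date"].map(lambda d: d.isoformat())
    eps.to_csv(directory / "true_episodes.csv", index=False)
    cfg = config.model_dump(mode="json")
    with open(directory / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return dataset, truth
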