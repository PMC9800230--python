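"""Cohort-level drug-utilisation metrics.

Aggregates per-patient chronic-use classifications into the study's
published quantities: prevalent and incident cohorts, incidence and
prevalence rates against general-population denominators, discontinuation
proportions with death accounting, age/sex demographics, defined-daily-dose
(DDD) totals, dispensation mix by molecule and strength, prescriber
attribution of initiations and first renewals, and a Cochran–Armitage trend
test across ordered study years.

Rounding everywhere is half-away-from-zero (the convention of printed
epidemiological tables), at one decimal for rates and ages and two decimals
for mix shares, both configurable per call.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .claims_io import ClaimsDataset, age_at
from .exposure import classify_statuses

__all__ = [
    "YearlyCohortSummary",
    "annual_ddd_per_patient",
    "build_yearly_summary",
    "cochran_armitage_trend",
    "demographics_summary",
    "discontinuation_summary",
    "dispensation_mix",
    "incident_chronic",
    "median_annual_ddd",
    "pooled_mean",
    "prescriber_attribution",
    "prevalent_chronic",
    "rate_pct",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (printed-table convention), not banker's."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rate_pct(count: int, population: int, decimals: int = 1) -> float:
    """``100 * count / population`` rounded half-away-from-zero."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return round_half_away(100.0 * count / population, decimals)


def pooled_mean(means, weights) -> float:
    """Size-weighted mean of per-year means: sum(w*m)/sum(w)."""
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if means.shape != weights.shape or means.size == 0:
        raise ValueError("means and weights must be equal-length, non-empty")
    return float(np.sum(means * weights) / np.sum(weights))


# ---------------------------------------------------------------------------
# cohorts


def _statuses_for(dataset: ClaimsDataset, year: int,
                  statuses: pd.DataFrame | None) -> pd.DataFrame:
    if statuses is None:
        statuses = classify_statuses(dataset.dispensings, dataset.patients, [year])
    sub = statuses[statuses["year"] == year]
    return sub


def prevalent_chronic(dataset: ClaimsDataset, year: int,
                      statuses: pd.DataFrame | None = None) -> set[str]:
    """Patients chronic on January 1 of ``year`` (the prevalent cohort)."""
    sub = _statuses_for(dataset, year, statuses)
    return set(sub.loc[sub["chronic"], "patient_id"])


def incident_chronic(dataset: ClaimsDataset, year: int,
                     statuses: pd.DataFrame | None = None) -> set[str]:
    """Chronic patients of ``year`` with no exposure on January 1 of the
    prior year (new users); a subset of the prevalent cohort."""
    sub = _statuses_for(dataset, year, statuses)
    return set(sub.loc[sub["incident"], "patient_id"])


def discontinuation_summary(dataset: ClaimsDataset, year: int,
                            statuses: pd.DataFrame | None = None,
                            decimals: int = 1) -> tuple[int, int, float]:
    """(discontinuer count, deaths before Oct 31 cutoff, proportion %).

    The numerator counts every chronic patient of the year without a
    November–December refill, *including* those who died on or before
    October 31 (tallied separately); the denominator is the prevalent count.
    """
    sub = _statuses_for(dataset, year, statuses)
    prevalent = int(sub["chronic"].sum())
    if prevalent == 0:
        raise ValueError(f"no prevalent chronic patients in {year}; "
                         "discontinuation proportion undefined")
    disc = sub[sub["discontinued"]]
    count = len(disc)
    deaths = int(disc["died_before_cutoff"].sum())
    return count, deaths, rate_pct(count, prevalent, decimals)


# ---------------------------------------------------------------------------
# DDD accounting


def annual_ddd_per_patient(patient_records: pd.DataFrame, year: int,
                           drug_reference: pd.DataFrame) -> float:
    """DDDs dispensed to one patient in a calendar year.

    Each oral dispensing contributes ``units * dosage_mg / ddd_mg``: a
    patient taking one DDD-strength unit daily all year accrues 365 DDD.
    """
    rec = patient_records[patient_records["route"] == "oral"]
    rec = rec[[d.year == year for d in rec["dispense_date"]]]
    if rec.empty:
        return 0.0
    ref = drug_reference.set_index(["inn", "dosage_mg"])["ddd_mg"]
    total = 0.0
    for _, row in rec.iterrows():
        key = (row["inn"], float(row["dosage_mg"]))
        if key not in ref.index:
            raise KeyError(f"no DDD entry for {key[0]} {key[1]:g} mg")
        total += row["units_dispensed"] * float(row["dosage_mg"]) / float(ref.loc[key])
    return total


def median_annual_ddd(dataset: ClaimsDataset, year: int,
                      patient_ids: set[str]) -> float:
    """Median annual DDD over a patient set (typically the prevalent cohort)."""
    if not patient_ids:
        raise ValueError("empty patient set")
    disp = dataset.dispensings
    disp = disp[(disp["route"] == "oral")
                & disp["patient_id"].isin(patient_ids)]
    disp = disp[[d.year == year for d in disp["dispense_date"]]]
    ref = dataset.drug_reference.set_index(["inn", "dosage_mg"])["ddd_mg"]
    ddd_per_unit = pd.Series(
        [float(row["dosage_mg"]) / float(ref.loc[(row["inn"], float(row["dosage_mg"]))])
         for _, row in disp.iterrows()], index=disp.index, dtype=float)
    per_patient = (disp["units_dispensed"] * ddd_per_unit).groupby(
        disp["patient_id"]).sum()
    # patients with no dispensing in the year contribute 0 DDD
    totals = per_patient.reindex(sorted(patient_ids), fill_value=0.0)
    return float(np.median(totals.to_numpy()))


# ---------------------------------------------------------------------------
# mix and prescribers


def dispensation_mix(dataset: ClaimsDataset, year: int,
                     chronic_ids: set[str] | None = None,
                     statuses: pd.DataFrame | None = None,
                     decimals: int = 2) -> dict[str, float]:
    """Share of dispensing events per molecule+strength among the year's
    chronic users, as percentages summing to ~100."""
    if chronic_ids is None:
        chronic_ids = prevalent_chronic(dataset, year, statuses)
    disp = dataset.dispensings
    disp = disp[(disp["route"] == "oral") & disp["patient_id"].isin(chronic_ids)]
    disp = disp[[d.year == year for d in disp["dispense_date"]]]
    if disp.empty:
        raise ValueError(f"no dispensings for chronic patients in {year}")
    labels = disp["inn"] + " " + disp["dosage_mg"].map(lambda d: f"{d:g}") + " mg"
    counts = labels.value_counts()
    total = int(counts.sum())
    return {k: round_half_away(100.0 * v / total, decimals)
            for k, v in sorted(counts.items())}


def prescriber_attribution(dataset: ClaimsDataset,
                           decimals: int = 1) -> pd.DataFrame:
    """Initiation and first-renewal counts and shares by prescriber specialty.

    Initiation: the prescriber of a patient's first dispensing anywhere in
    the loaded data (the data span is the look-back).  First renewal: the
    prescriber of the earliest dispensing bearing a prescription id different
    from the initiation prescription; patients whose every dispensing shares
    one prescription contribute no renewal.
    """
    disp = dataset.dispensings.sort_values(["patient_id", "dispense_date"])
    init_spec: list[str] = []
    renew_spec: list[str] = []
    for _, grp in disp.groupby("patient_id", sort=False):
        first = grp.iloc[0]
        init_spec.append(first["prescriber_specialty"])
        other = grp[grp["prescription_id"] != first["prescription_id"]]
        if not other.empty:
            renew_spec.append(other.iloc[0]["prescriber_specialty"])
    rows = []
    for kind, specs in (("initiation", init_spec), ("first_renewal", renew_spec)):
        total = len(specs)
        counts = pd.Series(specs).value_counts() if specs else pd.Series(dtype=int)
        for specialty in ("general_practitioner", "specialist", "institution"):
            c = int(counts.get(specialty, 0))
            rows.append({
                "kind": kind,
                "specialty": specialty,
                "count": c,
                "pct": rate_pct(c, total, decimals) if total else float("nan"),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trend test


def cochran_armitage_trend(counts, populations, scores=None) -> tuple[float, float]:
    """Cochran–Armitage score test for a linear trend in proportions.

    ``counts[i]`` events out of ``populations[i]`` at ordered score
    ``scores[i]`` (default 0,1,2,...).  Returns the standard-normal score
    statistic and its two-sided p-value; identical proportions give a
    statistic of ~0 and p of ~1.  Equivalent to the chi-square trend test
    (the statistic squared is the one-degree chi-square).
    """
    r = np.asarray(counts, dtype=float)
    n = np.asarray(populations, dtype=float)
    if r.shape != n.shape or r.size < 2:
        raise ValueError("need counts and populations for at least two groups")
    if (n <= 0).any():
        raise ValueError("populations must be positive")
    x = np.arange(r.size, dtype=float) if scores is None else np.asarray(scores, float)
    p_bar = r.sum() / n.sum()
    x_bar = (n * x).sum() / n.sum()
    num = ((x - x_bar) * r).sum()
    var = p_bar * (1 - p_bar) * (n * (x - x_bar) ** 2).sum()
    if var == 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# demographics


def _inclusive_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median (midpoint for even n) and Tukey inclusive quartiles."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def med(a: np.ndarray) -> float:
        m = a.size
        if m % 2:
            return float(a[m // 2])
        return float((a[m // 2 - 1] + a[m // 2]) / 2.0)

    median = med(v)
    if n == 1:
        return median, median, median
    if n % 2:  # inclusive: the median element belongs to both halves
        lower, upper = v[: n // 2 + 1], v[n // 2:]
    else:
        lower, upper = v[: n // 2], v[n // 2:]
    return med(lower), median, med(upper)


def demographics_summary(dataset: ClaimsDataset, patient_ids: set[str],
                         anchor_year: int, decimals: int = 1) -> dict:
    """Age and sex summary of a cohort at the January 1 anchor.

    Ages are completed years at Jan 1 of ``anchor_year``.  The standard
    deviation is the sample SD (0 for a single patient); the median uses the
    midpoint convention for even n and quartiles the inclusive method, so
    results are reproducible bit-for-bit.
    """
    if not patient_ids:
        raise ValueError("empty patient set")
    anchor = dt.date(anchor_year, 1, 1)
    pat = dataset.patients[dataset.patients["patient_id"].isin(patient_ids)]
    ages = np.array([age_at(b, anchor) for b in pat["birth_date"]], dtype=float)
    q1, median, q3 = _inclusive_quartiles(ages)
    male = int((pat["sex"] == "male").sum())
    n = len(pat)
    sd = float(np.std(ages, ddof=1)) if n > 1 else 0.0
    return {
        "n": n,
        "age_mean": round_half_away(float(np.mean(ages)), decimals),
        "age_sd": round_half_away(sd, decimals),
        "age_median": median,
        "age_iqr": q3 - q1,
        "male_count": male,
        "male_pct": rate_pct(male, n, decimals),
        "female_count": n - male,
        "female_pct": rate_pct(n - male, n, decimals),
    }


# ---------------------------------------------------------------------------
# the per-year rollup


@dataclass
class YearlyCohortSummary:
    """One study-year's counts, rates, demographics, DDD and mix statistics."""

    year: int
    prevalent_count: int
    incident_count: int
    discontinuation_count: int
    deaths_before_cutoff: int
    general_population: int
    incidence_rate_pct: float
    prevalence_rate_pct: float
    discontinuation_pct: float
    prevalent_demographics: dict = field(default_factory=dict)
    incident_demographics: dict = field(default_factory=dict)
    median_ddd_per_patient: float = float("nan")
    drug_mix: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "year": self.year,
            "prevalent_count": self.prevalent_count,
            "incident_count": self.incident_count,
            "discontinuation_count": self.discontinuation_count,
            "deaths_before_cutoff": self.deaths_before_cutoff,
            "general_population": self.general_population,
            "incidence_rate_pct": self.incidence_rate_pct,
            "prevalence_rate_pct": self.prevalence_rate_pct,
            "discontinuation_pct": self.discontinuation_pct,
            "median_ddd_per_patient": self.median_ddd_per_patient,
        }
        for prefix, demo in (("prevalent", self.prevalent_demographics),
                             ("incident", self.incident_demographics)):
            for k, v in demo.items():
                if k != "n":
                    row[f"{prefix}_{k}"] = v
        return row


def build_yearly_summary(dataset: ClaimsDataset, year: int,
                         statuses: pd.DataFrame | None = None,
                         rate_decimals: int = 1,
                         mix_decimals: int = 2) -> YearlyCohortSummary:
    """Compute the full per-year rollup from classifications."""
    if statuses is None:
        statuses = classify_statuses(dataset.dispensings, dataset.patients, [year])
    prevalent = prevalent_chronic(dataset, year, statuses)
    incident = incident_chronic(dataset, year, statuses)
    disc_count, deaths, disc_pct = discontinuation_summary(
        dataset, year, statuses, decimals=rate_decimals)
    population = dataset.population(year)
    return YearlyCohortSummary(
        year=year,
        prevalent_count=len(prevalent),
        incident_count=len(incident),
        discontinuation_count=disc_count,
        deaths_before_cutoff=deaths,
        general_population=population,
        incidence_rate_pct=rate_pct(len(incident), population, rate_decimals),
        prevalence_rate_pct=rate_pct(len(prevalent), population, rate_decimals),
        discontinuation_pct=disc_pct,
        prevalent_demographics=demographics_summary(dataset, prevalent, year,
                                                    rate_decimals),
        incident_demographics=(demographics_summary(dataset, incident, year,
                                                    rate_decimals)
                               if incident else {}),
        median_ddd_per_patient=median_annual_ddd(dataset, year, prevalent),
        drug_mix=dispensation_mix(dataset, year, prevalent, decimals=mix_decimals),
    )
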