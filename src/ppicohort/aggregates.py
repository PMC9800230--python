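"""Published aggregate tables from a French regional chronic-PPI
drug-utilisation study (Pays de la Loire, study years 2017–2020).

These are cohort-level counts as printed in the study's result tables —
incident and prevalent cohort sizes, general-population denominators,
per-year age summaries, male counts, discontinuation counts with the number
of patients who died before the October 31 cutoff, dispensation-mix
percentages by molecule and strength, prescriber renewal counts, and the
initiating-prescriber head-counts for non-GP specialties.  The underlying
individual-level claims are not public; these aggregates are the inputs of
the package's worked examples and arithmetic cross-checks (rates,
proportions, pooled means, trend test).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "INITIATING_OTHER_SPECIALTY_PRESCRIBERS",
    "RENEWAL_COUNTS",
    "STUDY_YEARS",
    "discontinuation_table",
    "dispensation_mix_table",
    "incident_table",
    "prevalent_table",
]

STUDY_YEARS = [2017, 2018, 2019, 2020]

_GENERAL_POPULATION = [3_757_600, 3_781_420, 3_800_000, 3_801_800]


def incident_table() -> pd.DataFrame:
    """Incident (new chronic user) cohort by year: size, age summaries,
    male counts and general-population denominators."""
    return pd.DataFrame({
        "year": STUDY_YEARS,
        "incident_count": [46_308, 47_684, 47_931, 77_222],
        "age_mean": [67.6, 68.0, 68.2, 66.4],
        "age_sd": [15.6, 15.7, 15.6, 15.7],
        "age_median": [69, 69, 70, 68],
        "age_iqr": [22, 22, 22, 21],
        "male_count": [20_562, 22_205, 21_812, 35_397],
        "general_population": _GENERAL_POPULATION,
    })


def prevalent_table() -> pd.DataFrame:
    """Prevalent chronic cohort by year."""
    return pd.DataFrame({
        "year": STUDY_YEARS,
        "prevalent_count": [156_721, 160_498, 164_721, 167_751],
        "age_mean": [70.6, 70.7, 70.9, 71.1],
        "age_sd": [14.6, 14.6, 14.5, 14.4],
        "age_median": [71, 72, 72, 72],
        "age_iqr": [20, 20, 20, 20],
        "male_count": [71_381, 73_033, 76_207, 77_775],
        "general_population": _GENERAL_POPULATION,
    })


def discontinuation_table() -> pd.DataFrame:
    """Chronic patients on Jan 1, discontinuers (no Nov–Dec refill) and the
    subset who died on or before Oct 31, by year."""
    return pd.DataFrame({
        "year": STUDY_YEARS,
        "prevalent_count": [156_721, 160_498, 164_721, 167_751],
        "discontinuation_count": [19_551, 20_761, 21_301, 20_809],
        "deaths_before_cutoff": [52, 71, 95, 131],
    })


def dispensation_mix_table() -> pd.DataFrame:
    """Share (%) of dispensing events among chronic users by molecule and
    strength, per year."""
    rows = [
        ("esomeprazole", 10, 0.12, 0.14, 0.14, 0.13),
        ("esomeprazole", 20, 22.31, 22.03, 21.87, 21.67),
        ("esomeprazole", 40, 17.88, 17.97, 17.78, 17.70),
        ("lansoprazole", 15, 6.75, 7.11, 7.70, 8.18),
        ("lansoprazole", 30, 5.84, 6.00, 6.21, 6.44),
        ("omeprazole", 10, 3.66, 3.69, 3.54, 3.49),
        ("omeprazole", 20, 14.73, 14.66, 14.14, 13.78),
        ("pantoprazole", 20, 12.02, 12.17, 12.65, 12.79),
        ("pantoprazole", 40, 7.57, 7.85, 7.87, 8.08),
        ("rabeprazole", 10, 3.74, 3.38, 3.20, 2.96),
        ("rabeprazole", 20, 5.39, 4.99, 4.89, 4.78),
    ]
    return pd.DataFrame(
        rows, columns=["inn", "dosage_mg", "pct_2017", "pct_2018",
                       "pct_2019", "pct_2020"])


#: First-renewal prescription counts 2017–2020 by prescriber group.
RENEWAL_COUNTS = {
    "general_practitioner": 2_402_263,
    "institution": 281_311,
    "specialist": 5_221,
}

#: Head-count of non-GP specialist physicians initiating chronic PPI
#: treatment, first and last study year.
INITIATING_OTHER_SPECIALTY_PRESCRIBERS = {2017: 61, 2020: 122}
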