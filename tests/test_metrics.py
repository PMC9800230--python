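"""Cohort metrics: rates, discontinuation accounting, DDD, mix, prescriber
attribution, trend test and demographics."""

import datetime as dt
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppicohort import aggregates
from ppicohort.metrics import (
    annual_ddd_per_patient,
    cochran_armitage_trend,
    demographics_summary,
    discontinuation_summary,
    dispensation_mix,
    incident_chronic,
    median_annual_ddd,
    pooled_mean,
    prescriber_attribution,
    prevalent_chronic,
    rate_pct,
    round_half_away,
)
from ppicohort.exposure import classify_statuses
from ppicohort.synthetic_claims import GeneratorConfig, generate_dataset

from conftest import make_dataset, make_dispensings, make_patients


class TestRatePct:
    @pytest.mark.parametrize("count,pop,expected", [
        (46_308, 3_757_600, 1.2),     # incidence, first study year
        (167_751, 3_801_800, 4.4),    # prevalence, last study year
        (19_551, 156_721, 12.5),      # discontinuation, first study year
        (20_809, 167_751, 12.4),      # discontinuation, last study year
        (0, 1000, 0.0),
    ])
    def test_published_rate_arithmetic(self, count, pop, expected):
        assert rate_pct(count, pop, 1) == expected

    def test_full_cohort_is_100_pct(self):
        assert rate_pct(123, 123) == 100.0

    @given(count=st.integers(0, 10_000), pop=st.integers(1, 10_000),
           k=st.integers(1, 50))
    @settings(max_examples=50, derandomize=True)
    def test_homogeneous_in_joint_scaling(self, count, pop, k):
        assert rate_pct(count, pop, 3) == rate_pct(k * count, k * pop, 3)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            rate_pct(1, 0)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(12.45, 1) == 12.5  # banker's would give 12.4
        assert round_half_away(0.125, 2) == 0.13


class TestCohortSets:
    @pytest.fixture
    def two_patient_dataset(self):
        patients = make_patients([
            ("A", dt.date(1950, 1, 1), "female", None, True),
            ("B", dt.date(1940, 1, 1), "male", None, True),
        ])
        disp = make_dispensings([
            ("A", dt.date(2016, 10, 20), 80),   # chronic + incident 2017
            ("A", dt.date(2017, 12, 1), 30),
            ("B", dt.date(2017, 3, 1), 10),     # never chronic
        ])
        return make_dataset(patients, disp, years=(2016, 2017), population=100)

    def test_prevalent_singleton(self, two_patient_dataset):
        assert prevalent_chronic(two_patient_dataset, 2017) == {"A"}

    def test_incident_subset_of_prevalent(self, two_patient_dataset):
        prev = prevalent_chronic(two_patient_dataset, 2017)
        inc = incident_chronic(two_patient_dataset, 2017)
        assert inc <= prev

    def test_empty_dataset_empty_incident_set(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        ds = make_dataset(patients, make_dispensings([]))
        assert incident_chronic(ds, 2017) == set()


class TestDiscontinuationSummary:
    def test_death_before_cutoff_included_in_numerator(self):
        patients = make_patients([
            ("A", dt.date(1950, 1, 1), "female", dt.date(2017, 9, 1), True),
            ("B", dt.date(1940, 1, 1), "male", None, True),
        ])
        disp = make_dispensings([
            ("A", dt.date(2016, 10, 20), 80),   # dies 2017-09-01: discontinuer
            ("B", dt.date(2016, 10, 20), 80),
            ("B", dt.date(2017, 11, 20), 30),   # refills in November: persists
        ])
        ds = make_dataset(patients, disp, years=(2016, 2017))
        count, deaths, pct = discontinuation_summary(ds, 2017)
        assert (count, deaths) == (1, 1)
        assert pct == 50.0

    def test_no_prevalent_patients_is_undefined(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        ds = make_dataset(patients, make_dispensings([]))
        with pytest.raises(ValueError, match="undefined"):
            discontinuation_summary(ds, 2017)


class TestDDD:
    def _records(self, rows):
        return make_dispensings(rows)

    def test_daily_ddd_strength_unit_for_a_year_is_365(self):
        # omeprazole 20 mg with ddd 20 mg: one unit is exactly one DDD
        rec = self._records([("A", dt.date(2017, 1, 1), 365)])
        ref = pd.DataFrame({"inn": ["omeprazole"], "dosage_mg": [20.0],
                            "ddd_mg": [20.0]})
        assert annual_ddd_per_patient(rec, 2017, ref) == pytest.approx(365.0)

    def test_half_strength_units_halve_the_ddd(self):
        rec = self._records([
            ("A", dt.date(2017, 2, 1), "omeprazole", 10.0, 100, "oral",
             "A-RX1", "general_practitioner")])
        ref = pd.DataFrame({"inn": ["omeprazole"], "dosage_mg": [10.0],
                            "ddd_mg": [20.0]})
        assert annual_ddd_per_patient(rec, 2017, ref) == pytest.approx(50.0)

    def test_no_dispensings_is_zero_ddd(self):
        ref = pd.DataFrame({"inn": ["omeprazole"], "dosage_mg": [20.0],
                            "ddd_mg": [20.0]})
        assert annual_ddd_per_patient(self._records([]), 2017, ref) == 0.0

    def test_median_over_patient_set(self):
        patients = make_patients([
            (pid, dt.date(1950, 1, 1), "female", None, True)
            for pid in ("A", "B", "C")])
        disp = make_dispensings([
            ("A", dt.date(2017, 1, 1), 100),
            ("B", dt.date(2017, 1, 1), 200),
            ("C", dt.date(2017, 1, 1), 300),
        ])
        ds = make_dataset(patients, disp)
        assert median_annual_ddd(ds, 2017, {"A", "B", "C"}) == pytest.approx(200.0)


class TestDispensationMix:
    def test_single_product_is_100_pct(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        disp = make_dispensings([("A", dt.date(2017, 3, 1), 30)])
        ds = make_dataset(patients, disp)
        assert dispensation_mix(ds, 2017, {"A"}) == {"omeprazole 20 mg": 100.0}

    def test_equal_event_counts_split_evenly(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        disp = make_dispensings([
            ("A", dt.date(2017, 3, 1), 30),
            ("A", dt.date(2017, 4, 1), "esomeprazole", 20.0, 30, "oral",
             "A-RX2", "general_practitioner"),
        ])
        ds = make_dataset(patients, disp)
        assert dispensation_mix(ds, 2017, {"A"}) == {
            "esomeprazole 20 mg": 50.0, "omeprazole 20 mg": 50.0}

    def test_shares_sum_to_100_within_rounding(self):
        dataset, _ = generate_dataset(GeneratorConfig(
            n_patients=400, seed=3, annual_new_chronic_probability=0.3))
        mix = dispensation_mix(dataset, 2018)
        assert sum(mix.values()) == pytest.approx(100.0, abs=0.1)
        assert all(v >= 0 for v in mix.values())


class TestPrescriberAttribution:
    def test_single_gp_initiation_full_share(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        disp = make_dispensings([("A", dt.date(2017, 3, 1), 30)])
        ds = make_dataset(patients, disp)
        table = prescriber_attribution(ds)
        gp_init = table[(table["kind"] == "initiation")
                        & (table["specialty"] == "general_practitioner")]
        assert gp_init["pct"].iloc[0] == 100.0

    def test_single_prescription_patient_has_no_renewal(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        disp = make_dispensings([
            ("A", dt.date(2017, 3, 1), 30),
            ("A", dt.date(2017, 4, 1), 30),   # same prescription id
        ])
        ds = make_dataset(patients, disp)
        table = prescriber_attribution(ds)
        assert table[table["kind"] == "first_renewal"]["count"].sum() == 0

    def test_renewal_prescriber_is_first_new_prescription(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        disp = make_dispensings([
            ("A", dt.date(2017, 3, 1), "omeprazole", 20.0, 30, "oral",
             "A-RX1", "general_practitioner"),
            ("A", dt.date(2017, 4, 1), "omeprazole", 20.0, 30, "oral",
             "A-RX2", "specialist"),
            ("A", dt.date(2017, 5, 1), "omeprazole", 20.0, 30, "oral",
             "A-RX3", "institution"),
        ])
        ds = make_dataset(patients, disp)
        table = prescriber_attribution(ds)
        renew = table[table["kind"] == "first_renewal"].set_index("specialty")
        assert renew.loc["specialist", "count"] == 1
        assert renew.loc["institution", "count"] == 0

    def test_published_renewal_shares(self):
        total = sum(aggregates.RENEWAL_COUNTS.values())
        shares = {k: rate_pct(v, total, 1)
                  for k, v in aggregates.RENEWAL_COUNTS.items()}
        assert shares == {"general_practitioner": 89.3, "institution": 10.5,
                          "specialist": 0.2}


class TestTrendTest:
    def test_flat_proportions_give_null_result(self):
        z, p = cochran_armitage_trend([10, 20, 30], [100, 200, 300])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_published_incidence_trend_is_significant(self):
        inc = aggregates.incident_table()
        z, p = cochran_armitage_trend(inc["incident_count"],
                                      inc["general_population"])
        assert p < 1e-4
        assert z > 0  # rising trend

    def test_agrees_with_permutation_oracle(self):
        counts, pops = [3, 5, 9], [20, 20, 20]
        z_obs, p_norm = cochran_armitage_trend(counts, pops)
        # exhaustive relabelling within the score statistic's null:
        # permute group membership of all 60 subjects, Monte-Carlo
        rng = np.random.default_rng(0)
        subjects = np.repeat([0, 1, 2], 20)
        outcomes = np.concatenate([
            np.r_[np.ones(c), np.zeros(n - c)] for c, n in zip(counts, pops)])
        stats = []
        for _ in range(20_000):
            perm = rng.permutation(outcomes)
            c_perm = [perm[subjects == g].sum() for g in range(3)]
            z, _ = cochran_armitage_trend(c_perm, pops)
            stats.append(abs(z) >= abs(z_obs) - 1e-12)
        p_perm = np.mean(stats)
        assert p_norm == pytest.approx(p_perm, abs=0.02)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage_trend([1, 2], [10, 0])


class TestDemographics:
    def test_pooled_incident_mean_age_from_published_tables(self):
        inc = aggregates.incident_table()
        pooled = pooled_mean(inc["age_mean"], inc["incident_count"])
        assert round_half_away(pooled, 1) == 67.4

    def test_pooled_mean_equal_weights_is_arithmetic_mean(self):
        vals = [1.0, 2.0, 4.0]
        assert pooled_mean(vals, [5, 5, 5]) == pytest.approx(np.mean(vals))

    def test_published_incident_female_share(self):
        inc = aggregates.incident_table()
        female = (inc["incident_count"] - inc["male_count"]).sum()
        assert rate_pct(int(female), int(inc["incident_count"].sum()), 1) == 54.4

    def test_single_patient_degenerate_summary(self):
        patients = make_patients([("A", dt.date(1967, 1, 1), "female", None, True)])
        ds = make_dataset(patients, make_dispensings([]))
        s = demographics_summary(ds, {"A"}, 2017)
        assert (s["age_mean"], s["age_median"], s["age_sd"]) == (50.0, 50.0, 0.0)

    def test_two_patient_midpoint_median(self):
        patients = make_patients([
            ("A", dt.date(1957, 1, 1), "female", None, True),
            ("B", dt.date(1947, 1, 1), "male", None, True),
        ])
        ds = make_dataset(patients, make_dispensings([]))
        s = demographics_summary(ds, {"A", "B"}, 2017)
        assert s["age_mean"] == 65.0
        assert s["age_median"] == 65.0
        assert s["male_pct"] == 50.0

    def test_empty_set_rejected(self):
        patients = make_patients([("A", dt.date(1950, 1, 1), "female", None, True)])
        ds = make_dataset(patients, make_dispensings([]))
        with pytest.raises(ValueError):
            demographics_summary(ds, set(), 2017)
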