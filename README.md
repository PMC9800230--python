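# ppicohort

Chronic proton-pump-inhibitor (PPI) use and deprescribing on longitudinal
pharmacy-dispensing claims.

PPIs are among the most prescribed drug classes, and a large share of their
chronic community use is inappropriate. Measuring whether deprescribing is
actually happening requires a reproducible pipeline that turns raw dispensing
claims into annual cohorts of chronic users, discontinuation proportions,
treatment episodes and consumption statistics. Real claims extracts of this
kind (e.g. from national health-insurance databases) are confidential, so
`ppicohort` pairs the analysis with a seeded synthetic claims generator that
plants known ground truth, letting the whole pipeline run — and be validated —
without access to protected data.

It is intended for pharmacoepidemiologists and drug-utilization researchers
designing or benchmarking deprescribing studies on dispensing data.

## The model

One dispensed unit is one oral daily dose, so a dispensing of *u* units on day
*d* supplies the closed interval [*d*, *d* + *u* − 1].

- **Chronic user (year *n*)** — at least ⌈0.80 × 92⌉ = **74 doses** dispensed
  during the trailing quarter Oct 1 – Dec 31 of year *n* − 1 (≥ 80% temporal
  coverage of the 92-day window), evaluated at the January 1 anchor.
- **Chronic incident (new user)** — chronic in year *n* with no supply
  interval covering January 1 of year *n* − 1.
- **Discontinuation** — a chronic user of year *n* with no oral dispensing
  dated in November–December of year *n*; deaths on or before October 31 are
  tallied separately within the discontinuers.
- **Episode** — a maximal union of supply intervals; an uncovered run of
  ≥ 61 days (two months) ends an episode, and a later dispensing starts a new
  one.
- **DDD accounting** — each dispensing contributes
  `units × dosage_mg / ddd_mg` defined daily doses; annual totals and cohort
  medians summarise consumption intensity.
- Incidence/prevalence rates are `100 × count / population` against yearly
  general-population denominators; the across-year trend is tested with a
  Cochran–Armitage score test.

## Worked example

```python
from ppicohort import GeneratorConfig, generate_dataset, classify_statuses
from ppicohort.metrics import build_yearly_summary

config = GeneratorConfig(n_patients=2000, seed=11,
                         annual_new_chronic_probability=0.05)
dataset, truth = generate_dataset(config)
statuses = classify_statuses(dataset.dispensings, dataset.patients,
                             config.classification_years)
summary = build_yearly_summary(dataset, 2019, statuses)
print(f"2019: prevalent={summary.prevalent_count} "
      f"incident={summary.incident_count} "
      f"discontinued={summary.discontinuation_count} "
      f"({summary.discontinuation_pct}%) "
      f"prevalence={summary.prevalence_rate_pct}% "
      f"median DDD={summary.median_ddd_per_patient:.0f}")
```

prints

```
2019: prevalent=244 incident=116 discontinued=38 (15.6%) prevalence=12.2% median DDD=220
```

244 patients were chronic users on 2019-01-01 (≥ 74 doses in Oct–Dec 2018);
116 of them were new users; 38 (15.6% of the prevalent cohort) took no refill
in Nov–Dec 2019 and so discontinued; prevalence is measured against the
synthetic panel as its own denominator; the median prevalent patient received
220 DDD that year. The generator's `truth` object carries the planted labels
these classifications are checked against in the test suite.

The same analysis runs from a shell:

```bash
ppicohort simulate --out data/ --n-patients 2000 --seed 11
ppicohort run --data data/ --out results/ --log-level WARNING
```

which writes `chronic_status.csv`, `episodes.csv`, `yearly_summary.csv`,
`mix.csv`, `prescribers.csv`, `sensitivity.csv` and a run manifest, and prints
plain-text analogs of the study tables. Reruns with the same config and seed
are byte-identical.

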