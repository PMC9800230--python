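# Methods

## Exposure model

The analysis operates on reimbursed dispensing events, not prescriptions or
ingestion. Its single structural assumption is that **one dispensed unit is
one day of oral treatment**: a dispensing of *u* units on day *d* supplies the
closed day interval [*d*, *d* + *u* − 1]. This is the only reading under which
"74 doses over three consecutive months" and "80% temporal coverage" of a
92-day quarter coincide, and it makes all downstream quantities integer-exact.
Dose intensity in milligrams never enters exposure classification; it enters
only DDD accounting. All five PPI molecules are pooled, so switching between
them is invisible to coverage.

### Chronic status

Chronic status is evaluated **only at January 1 anchors** against the fixed
trailing window October 1 – December 31 (92 days) of the prior year — not as a
rolling three-month scan. A patient is chronic in year *n* when the units
dispensed inside that window total at least ⌈t × 92⌉ with t = 0.80, i.e. 74
doses. Coverage is **dose-count based** (units in window ÷ window days, capped
at 1), not supply-interval overlap; supply intervals are used only to decide
"user on a given day". Windows are closed on both ends: a dispensing dated
exactly October 1 or December 31 counts. At an arbitrary threshold the dose
cut-off is ⌈t × 92⌉, which reproduces 74 at 0.80 and cannot undershoot the
coverage fraction with integer doses (cut-offs 69 and 79 at 0.75 and 0.85).

The dataset-level classifier additionally requires the patient to be **alive
on the anchor date**; a corpse cannot be a prevalent cohort member, and the
published death accounting presupposes cohort membership on January 1. The
single-patient helper functions operate on records alone and do not take a
death date.

### Incident status and left truncation

A chronic user of year *n* is incident when no supply interval in the loaded
records covers January 1 of year *n* − 1. The loaded data span **is** the
look-back: exposure before the first record cannot be observed. With a data
period starting October 1 of the entry year, every chronic patient of the
first classification year is therefore classified incident — first-year
incidence is left-truncated and should be read as an upper bound. The same
limitation applies to "initiation" in prescriber attribution (first dispensing
anywhere in the loaded data).

### Discontinuation and episodes

A chronic user of year *n* discontinues when no oral dispensing is dated in
November–December of year *n* (61 days, the study's "two months"). The
discontinuation numerator **includes** patients who died on or before
October 31, tallied separately: this is the only convention under which the
published discontinuer counts divided by prevalent counts reproduce the
published one-decimal percentages. Episodes merge supply intervals while
uncovered runs are shorter than 61 days; a ≥ 61-day uncovered run followed by
a dispensing starts a new episode. Episode segmentation is invariant to input
record order.

The bundled published table prints two-decimal discontinuation percentages for
the middle study years that are not exactly recoverable from its own printed
counts under any single rounding rule; the one-decimal values are. The
pipeline computes both precisions from counts and asserts only the one-decimal
values.

## Aggregation choices

- Age is completed years at the January 1 anchor; "adult" means ≥ 18 there.
  Patients under 18 and patients with only parenteral dispensings are
  excluded; mixed-route patients are retained with their parenteral rows
  dropped from dose counting (community coverage should not be padded with
  hospital parenteral doses).
- Rounding is half-away-from-zero (printed-table convention): rates and ages
  at one decimal, mix shares at two, both configurable.
- Medians use the midpoint convention for even n and quartiles the inclusive
  (Tukey) method, so summaries are reproducible bit-for-bit. The sample SD is
  reported, with SD = 0 for a singleton cohort.
- The across-year trend test is the Cochran–Armitage score test (two-sided
  normal p), the standard test for proportions against ordered years. It is
  implemented directly — roughly fifteen lines — because the installed
  scientific stack exposes no equivalent; tests cross-check it against a
  permutation oracle.
- DDD values per molecule/strength are a user-supplied reference table. The
  bundled defaults (e.g. omeprazole 20 mg/day) are a plausible example
  fixture, not asserted agency values.

## Synthetic claims generator

The generator emulates a regional multi-year claims extract: an adult
age/sex structure (normal ages truncated at 18; Bernoulli sex), annual onset
of chronic use, an annual discontinuation hazard applied to patients in
treatment on January 1, resumption after discontinuation with its own
probability, rare deaths, a molecule×strength mix, and a GP-dominated
prescriber mix with a new prescription every third fill.

Within a treatment period, 30-unit boxes are dispensed at intervals of
`round(box / adherence) + jitter(0–4)` days, with per-patient adherence drawn
from a Beta distribution (mean 0.92, SD 0.05, clipped to [0.80, 0.99]).
Because refill lumpiness could still leave a planted chronic quarter below 74
units, the generator tops the window up with one extra dispensing — top-ups
are legitimate claims rows, not label edits. Planted discontinuations place
the last fill no later than mid-October; planted resumptions start no earlier
than February 1 of a later year, so every between-episode gap exceeds 61
uncovered days by construction while within-episode gaps stay far below it.

Ground-truth labels are **recomputed from the emitted records** with direct
window arithmetic that is independent of the classification module; they are
exact properties of the data, which is why classifier/generator agreement is
asserted as frame equality, not statistically.

Default rates mirror the emulated study's magnitudes: 1.5%/year onset (the
published incidence range is 1.2–2%), a 12.5% annual discontinuation hazard,
a 54.4% female share, the published 2017 dispensation mix, and a death
probability of 0.1%/year — deliberately small, matching the scale of the
published deaths-before-cutoff tallies relative to cohort size. One PRNG
stream is derived per patient from (seed, patient index), so adding patients
never perturbs existing ones and outputs are byte-identical across runs.

### What the generator does not emulate

Seasonality, molecule switching, dose titration, co-prescription (e.g. with
NSAIDs), indications, regional structure, the published absolute cohort
sizes, and the entry-year stock of long-standing users (all first episodes
start inside the study window, so first-year incidence equals prevalence, the
left-truncation behaviour described above). Passing tests therefore validate
the classification algebra and the statistical recovery of planted rates,
not distributional realism of real claims.

## Experiment sizes

Structural test fixtures use a few hundred patients with elevated onset
probability (0.25/year) so that every label type occurs; oracle-equivalence
checks run 200 randomized mini-datasets of up to 20 patients against a
brute-force patient-day grid. Parameter-recovery experiments use n = 10,000
patients with onset 0.15/year — chosen in advance so roughly ten thousand
chronic patient-years exist and three binomial standard errors of the planted
discontinuation probabilities {0.05, 0.125, 0.25} span about one percentage
point. Death probability is zeroed in those experiments because deaths are a
separate, additive source of refill-free autumns and would bias hazard
recovery upward by construction.

## Numerical and degenerate-input conventions

- Empty record sets count zero doses; classification of a year whose window
  leaves the declared data period raises.
- An empty cohort has no defined demographics or discontinuation proportion
  (errors, not NaNs).
- Threshold sensitivity counts are non-increasing in the threshold by
  construction of the ceiling cut-off.
- Report bundles are written with stable row order and ISO dates; the run
  manifest echoes the full config, seed, package version and row counts, and
  rerunning a config into the same directory is byte-identical.
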