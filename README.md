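# actireid

Reidentification risk analysis for deidentified wearable-device activity
data.

Minute-resolution accelerometer records ("counts" from a hip-worn
monitor, seven days per person) are routinely shared after removal of
protected health information, often after *partial temporal
aggregation* — summing the minute counts into k-minute windows. This
package implements, end to end, the attack that tests whether such
records remain linkable across time periods: demographic attributes act
as a quasi-identifier that partitions records into blocks, and a
multiclass matcher trained on each block's early-week activity
day-vectors is used to name the record behind each late-week
day-vector. The pipeline is aimed at privacy researchers and data
custodians who want to quantify, before release, how much protection a
given aggregation level actually provides.

## The method

For each record *i* with demographic key *d(i)* (age, sex, education,
household income, race/ethnicity, country of birth), the Monday–Friday
minute series is aggregated into windows of width *k* (default 20 min,
so each day is a vector in ℕ⁷²). Training uses Monday–Wednesday, testing
Thursday–Friday. Within every demographic block a multiclass classifier
*f_d* : ℝ^(1440/k) → record ids is fit with one sample per (record, day)
— either a linear SVM (one-vs-rest, five penalty/loss variants and cost
C ∈ {0.01, …, 100} selected by leave-one-day-out cross-validation) or a
random forest (candidate-features-per-split tuned the same way). A test
record is routed to the block matching its demographics, per-day class
scores are averaged, and the argmax is the predicted identity; the
demographics-only baseline predicts the lowest id in the block.

Matching success is tested against the chance null: under "all matches
are luck", the number of correct matches is Binomial(n, 1/N) with N the
candidate pool size; the package reports the exact upper-tail p-value
with Bonferroni adjustment over the experiment grid. Sensitivity
analyses cover the aggregation sweep (15 min to 24 h), alternative
weekday train/test splits, and a 60/20/20 partial-overlap scenario with
confidence-calibrated abstention, where correctly declaring "no match"
on a record absent from training counts as success.

Because the underlying national survey files are an external download,
the package ships a synthetic cohort generator that reproduces the
structure the attack exploits — stable individual diurnal signatures,
heavy-tailed counts (SD ≫ mean), hard sleep windows, demographic
marginals resembling the survey, and injectable data defects — plus an
optional, untested adapter (`actireid.nhanes`) for the real files.

## Worked example

```python
from actireid.simulate import (MODERATE_AGE_BIN_YEARS, generate_cohort,
                               moderate_signal_config)
from actireid.preprocess import prepare_cohort
from actireid.sensitivity import sweep_aggregation
from actireid.evaluate import adjust_results

cohort, log = prepare_cohort(generate_cohort(moderate_signal_config(n=100, seed=0)))
results = sweep_aggregation(cohort, intervals=(20,),
                            modes=("svm", "rf", "demographics_only"),
                            seed=0, age_bin_years=MODERATE_AGE_BIN_YEARS)
adjust_results(results)
for r in results:
    print(f"{r.labels['mode']:>18}: {r.n_matched}/{r.n_test} "
          f"({100 * r.accuracy:.1f}%), adjusted p = {r.p_adj:.2e}")
```

prints

```
               svm: 92/100 (92.0%), adjusted p = 6.87e-173
                rf: 87/100 (87.0%), adjusted p = 2.50e-158
 demographics_only: 48/100 (48.0%), adjusted p = 2.23e-67
```

Demographics alone reidentify about half of this cohort (blocks hold a
handful of records each); adding the 20-minute activity vectors lifts
the linkage to ~90%, and both are overwhelmingly above the 1% chance
level — the signature privacy failure this attack demonstrates. The
same drivers live under `analysis/` (`01_simulate_cohort.py` …
`05_partial_overlap.py`), each writing its table to `results/`, and a
`actireid` CLI exposes `simulate`, `attack`, `evaluate` and `sweep`
subcommands.

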