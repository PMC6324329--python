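# Methods

## Problem and pipeline

The package quantifies the reidentifiability of deidentified,
partially aggregated physical-activity records. Two datasets derived
from the same cohort but from disjoint weekdays play the roles of the
identified reference (training: record id, demographics, activity) and
the deidentified release (testing: demographics and activity only). The
attack succeeds on a record when the predicted training id equals the
true id.

Stages: (1) exclusions — records whose week is incomplete or whose
minute series has zero variance are dropped (the variance test uses the
full 7-day series, before weekday selection, since a constant week is a
device artifact regardless of which days are later used); (2)
imputation; (3) adult/child split at age 18; (4) restriction to
Monday–Friday; (5) aggregation of each day's 1440 minute counts into
left-aligned k-minute windows (window j covers minutes jk+1…(j+1)k, so
window sums conserve the day total exactly); (6) train/test
construction by weekday (default Mon–Wed vs Thu–Fri); (7) blocked
matching; (8) exact binomial inference.

## Imputation

Missing education, income and country of birth are replaced by the
mean of the valid coded values (education 1–2, income 1–3, birth
country 1–2) rounded to the nearest integer, computed over the cohort
being processed (per population, per dataset). Ties round half up; the
rule is arbitrary but must be fixed, and it is asserted in the tests.
Country of birth is included because the blocking key requires fully
observed attributes; its missingness is rare (≈0.02% in the marginals
used). Non-missing values are never altered. 18–19-year-olds whose
education was recorded on a child (highest-grade) scheme are mapped to
the adult two-level scheme with any pre-college grade → "high school or
less" (`recategorize_child_education`); the exact collapse is not
standardized, so it is kept as an explicit, replaceable function.

## The blocked matcher

Each demographic combination (age in integer years by default —
configurable binning via `age_bin_years` — plus sex, education, income,
race/ethnicity, birth country) defines one block; a separate multiclass
classifier is trained per block with the record id as the class. Days
are treated as samples: each training day contributes one
1440/k-dimensional vector, which is the only reading that puts training
(3 days) and testing (2 days) in a common feature space. Within a block
the demographic predictors are constant, so they are not appended to
the feature vector — blocking itself realizes "demographics as
predictors". Test-day class scores are averaged and the argmax
returned; all ties break to the lowest record id for determinism, and a
test demographic key absent from training yields NO_MATCH.

* SVM mode: `LinearSVC` one-vs-rest, choosing among the five classical
  linear-SVC formulations (L2-reg/L2-loss dual and primal,
  L2-reg/L1-loss, Crammer–Singer, L1-reg/L2-loss) × cost
  C ∈ {0.01, 0.1, 1, 10, 100} by leave-one-training-day-out
  cross-validation (3-fold under the default split — with three samples
  per class, day-wise folds are the only stratification that keeps every
  class in every training fold). Features are standardized per block
  before the SVM. Decision values are softmax-normalized into [0, 1]
  confidences.
* RF mode: random forest, 50 trees, tuning the candidate-feature count
  per split over {√p, p/3, p/2, p} by the same day-wise CV; confidence
  is the vote fraction. Fifty trees is the package's desk-scale default:
  at the block sizes produced here (a handful to a few hundred
  day-rows), accuracy plateaus well below the classical 500-tree
  default while keeping full grids tractable.
* Demographics-only mode: no activity features; the prediction is the
  lowest id in the block, so accuracy is exactly the number of blocks
  whose lowest training id occurs in testing (asserted as an identity in
  the tests).
* Activity-only runs are SVM/RF with `blocking="none"` (one block).

Grid ties in CV resolve to the earliest grid entry; per-block random
states derive deterministically from the run seed and the block index.

## Statistical evaluation

With candidate pool size N (training individuals; testing individuals
under partial overlap), the match count under the chance null is
Binomial(n_test, 1/N). The package computes the exact upper tail
P(X ≥ matches) — cheap at these sizes and free of approximation
ambiguity — and Bonferroni-adjusts by m = the number of cells in the
executed experiment grid, reporting m alongside. Significance is read
at α = .05.

## Partial overlap and abstention

Record ids are partitioned 60/20/20 (both periods / training only /
testing only) by a seeded draw. Correctly predicting NO_MATCH on a
testing-only record counts as a correct match. The abstention threshold
τ is chosen on calibration data the attacker can actually construct:
one training day (Wednesday) is reserved; a calibration model is
trained on Mon–Tue rows of a random 75% of training records; the
held-out 25% play the absent role on the reserved day; τ maximizes
calibration accuracy over the grid {0, 0.05, …, 1} (lowest maximizer).
The final model is refit on all three training days. The confidence
measure itself (softmax / vote share) is a design choice — no standard
exists for this calibration — and the exact-accounting limits τ = 0 and
τ > 1 are asserted in the tests.

## The synthetic cohort generator

The generator produces the minimal structure that makes this attack
work, with everything tunable:

* Per-minute mean `wake_i(t) · (base(t) + s · m_i · sig_i(t))`: a
  shared diurnal base curve (Gaussian bump peaking 14:00, floor 0.3,
  amplitude 220 counts for adults, 260 for children — children are the
  more active population); an individual signature `sig_i` of K = 8
  Gaussian bumps (random centers in waking hours, widths 30–120 min) —
  smooth, persistent "habit times", identical across all seven days; an
  individual activity-level multiplier `m_i` (lognormal, σ = 0.7); and
  the signature strength s scaling every individual-specific term.
* Sleep: a hard zero window 23:00–06:30 with an individual phase offset
  (uniform ±45 min) that is also scaled by s. The offset is part of the
  latent identity — were it independent of s, a cohort with s = 0 would
  still be identifiable through sleep timing and the chance-null
  property would be false by construction.
* Noise: a per-day lognormal multiplier (σ = `day_noise_scale`, default
  0.35) times per-minute lognormal noise with
  σ = `day_noise_scale · count_dispersion` (default 0.35 · 4 = 1.4),
  both unit-mean; counts are the rounded, floored-at-zero result. Thus
  `day_noise_scale = 0` yields exactly repeating noiseless days, and
  `count_dispersion` sets how heavy the minute-level tail is.
* Demographics: attributes sampled independently from marginals taken
  from a national accelerometer sample (adult male share 48.2%, etc.);
  ages integer truncated-normal (adults 40.0 ± 20.6 on 18–84, children
  12.3 ± 3.4 on 6–17). `identical_demographics_config` collapses all
  attributes and fixes age, removing all blocking information.
* Defects: seeded fractions of records are truncated to 1–6 days or
  replaced by constant all-zero weeks, exercising the exclusion stage.

Default calibration (chosen once, as the generator's definition of a
realistic cohort): minute counts average ≈ 230–270 with SD/mean ≈ 4 —
order-of-magnitude agreement with published daily intensity moments of
hip-worn monitors, where the SD is several times the mean — and, on the
moderate-blocking study condition below, 20-minute combined accuracy
lands mid-range (≈ 0.8 rather than ceiling or chance), so both
improvements and degradations remain visible.

Study conditions used by the tests and the acceptance script:

* noiseless (`day_noise_scale=0`, no sleep jitter): every matcher must
  be perfect and agree with a nearest-centroid 1-NN oracle;
* chance null (`identical_demographics_config`, s = 0): accuracy within
  binomial noise of 1/n, rare rejections of the null;
* moderate blocking (`moderate_signal_config` + age collapsed to a
  single bin, `MODERATE_AGE_BIN_YEARS`): with default marginals and
  age in years, a desk-scale cohort (n ≈ 200) fragments into singleton
  blocks and demographics alone reidentify nearly everyone — a ceiling
  the full-size survey does not hit. Collapsing age leaves ~60–70
  blocks of a few records each, reproducing the informative-but-
  insufficient blocking regime in which the combined-vs-demographics
  comparison is meaningful.

What the generator does **not** emulate: weekday/weekend contrast
(weekend days are statistically identical to weekdays, so weekday
selection is exercised only mechanically); wear-time gaps and non-wear
zeros beyond the sleep window; demographic correlations (attributes are
independent; a joint table can be passed as marginals of a single
fused attribute if needed); seasonal or secular trends; and any
calibration to a specific real dataset beyond the order-of-magnitude
moments above. Passing tests therefore demonstrate the pipeline's
correctness and the qualitative signal/noise/blocking trade-offs, not
the numeric accuracy one would obtain on real survey data.

## Numerical and determinism choices

Exact integer counts end to end (aggregation is integer summation, so
conservation is exact, not approximate). `LinearSVC` capped at 5000
iterations; convergence warnings suppressed — at 3 samples per class
the dual problems are tiny and the cap is never the binding constraint
in practice. All orderings (record ids, block keys, grid entries) are
sorted, every stochastic component takes an explicit seed, and report
bundles are byte-identical across reruns; record ids are zero-padded so
lexicographic tie-breaking matches numeric order.

## Problem sizes

The test-suite and acceptance-script cohorts use n = 50–200 individuals
and 5–10 seeds per stochastic claim. These are the package's chosen
desk-scale study conditions: large enough that binomial standard errors
separate the regimes being compared, small enough that the full grids
(five SVM variants × five costs, four forest feature counts, ten
aggregation widths, six day splits) run on a single CPU in minutes.

## Known limitations

* The NHANES adapter maps the public survey file schemas by
  configuration but is untested against live downloads.
* Blocking on exact age makes the demographic key nearly unique at
  small n; analyses at desk scale should use `age_bin_years` (the
  moderate condition does).
* The abstention calibration assumes the attacker knows the expected
  overlap fraction approximately (the 75/25 pseudo-split); other priors
  change τ.
* Bonferroni m is the executed grid size; comparisons across runs with
  different grids should use `p_raw`.
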