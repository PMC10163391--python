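# Methods

## Model

`gapscore` treats condition prioritisation as a multicriteria decision
problem.  Each medical condition is an *alternative*; each measurable
quantity — a mortality rate, a spending total, a count of granted patents —
is a *criterion* with a direction (gap-increasing for burden and cost,
gap-decreasing for innovation activity).  TOPSIS converts the matrix into a
score in [0, 1] per alternative: the relative Euclidean closeness to the
anti-ideal reference point after column normalisation and weighting,
`G = d⁺ / (d⁺ + d⁻)`.  A condition identical to the ideal (lowest burden,
lowest cost, highest innovation) scores 0; one identical to the anti-ideal
scores 1.

Scoring is hierarchical by default: one TOPSIS run per domain produces
burden, cost, and innovation scores (each oriented so that *more of that
domain's quantity* gives a higher score), and a second 3-criterion TOPSIS
run over the domain-score triples — burden and cost gap-increasing,
innovation gap-decreasing, equal domain weights — yields the overall gap.
A `flat` mode instead pools every raw criterion into a single matrix with
each domain's criteria sharing that domain's weight mass; the two modes
agree on planted-structure fixtures but are not numerically identical.
Hierarchical is the default because the domain scores are themselves
reportable quantities and make the integration step auditable.

### Domain matrices

For each domain the criteria are:

* the **cross-sectional value** of each metric at the domain's reference
  year (burden 2019, cost 2016); for innovation, where activity is noisy and
  annual, the mean over the 2015–2019 window;
* a **trend criterion** per metric over the domain window (burden
  2015–2019, cost 2012–2016, innovation 2015–2019), entered as relative
  change for rates and counts and absolute change for dollar totals —
  relative change is undefined at a zero start value and is then treated as
  missing;
* for burden, the **disparity summary rate ratio** per stratified metric:
  the mean rate of the non-reference groups over the most favorable group's
  rate, oriented ≥ 1, maximised over stratifications (sex, age,
  race/ethnicity).  A zero most-favorable rate makes the ratio undefined;
  the pipeline records a warning and treats the value as missing.

Missing cells are resolved by a configurable policy: `zero` (default —
treats an unrecorded quantity as absent activity/burden, analogous to "no
recorded deaths"), `drop_criterion`, or `mean_impute`.  Trend columns can be
negative, but TOPSIS input is required nonnegative here, so any column with
a negative minimum is shifted by that minimum before normalisation; under
min–max normalisation the shift is exactly neutral, under vector
normalisation it mildly compresses relative differences, which we accept for
the default configuration.  Columns that end up identically zero carry no
ranking information and are dropped with a warning.

## Numerical choices

* **Normalization**: vector (root-sum-square) by default — the classic
  TOPSIS choice, invariant to units per column; min–max available for
  sensitivity analysis, with constant columns mapped to 0.5.
* **Distance**: Euclidean, fixed.
* **Degenerate matrices**: if every alternative is identical both
  separations vanish and all scores are 0.5.
* **Weights** are sum-normalised, so only ratios matter; all-equal weights
  are the default at both levels (domain weights of 1 each; within-domain
  weights equal unless configured).
* **Ties in ranking** break by condition name ascending, making ranks
  deterministic.
* **Quartiles** for tiering use linear interpolation between order
  statistics (numpy's `linear` method, configurable); tiers use strict
  inequalities, so a score exactly at Q1 or Q3 is middle.  Tiering requires
  at least 4 conditions and is skipped (with a warning) below that.
* **Opportunity rule**: innovation tier low AND (burden tier not low OR
  cost tier not low).  The high-cost/high-innovation combination is
  annotated as the cost–innovation paradox but never flagged, since its
  costs may be driven by the innovation itself.
* **Dominant factor** in the narrative report is the largest of the burden
  score, the cost score, and the innovation *deficit* (1 − innovation
  score); all-equal candidates give "no dominant domain".

## Report-only ingestion

The raw metric tables behind the published 13-condition pilot composites
were never deposited, and the exact criterion roster and scaling behind the
printed domain scores is therefore unknowable; applying the standard TOPSIS
conventions above to the printed domain-score columns does not reproduce the
printed overall column exactly.  The package consequently treats the printed
table as an *ingestible worked example*: `rank_pilot()` /
`gapscore run --mode report-only` rank, tier, and flag precomputed scores
without re-deriving them.  When a score table lacks the overall column, the
hierarchical integration recomputes it.

## Synthetic data generator

All pilot metrics are positive and right-skewed, so the generator draws
`log value = μ_metric + b(condition, metric) + drift·(year − y₀) + ε`, with
a per-condition/metric normal random effect `b` (σ = 0.5) creating stable
between-condition differences, a small per-series linear drift (mean 0.03,
σ = 0.05 per year) so trend criteria are informative, and year-to-year
noise (σ = 0.2).  Counts (patents, deals, trials, approvals) are Poisson
with the log-normal value as rate, keeping them integral; rates and dollar
amounts stay continuous.  Metric locations are round magnitudes typical of
US national condition-level data (mortality ~50/100k, prevalence ~5 000/100k,
total spending ~$60B, patents ~600/yr).  Stratified mortality rates are
emitted at the burden reference year for three stratifications with a
configurable between-group rate ratio (default 1.5, group noise σ = 0.05),
so the computed disparity ratios concentrate near the configured value.

A planted gap condition is shifted by `gap_effect × σ_condition` (default
4 standard deviations) upward on every burden and cost metric and downward
on every innovation metric; a planted paradox condition is shifted upward on
cost *and* innovation.  With the default four-sigma effect the planted
condition is recovered at rank 1 in essentially all replicates; with no
effect, every condition is exchangeable and any fixed condition ranks first
about 1/n of the time — both properties are exercised by the test suite at
200 replicates.

What the generator does **not** emulate: calibration to actual IHME/NCHS/
GHED magnitudes or correlations between metrics beyond the shared condition
effect, time-series autocorrelation beyond linear drift, incomplete
racial/ethnic strata, and reporting artifacts (revisions, suppression of
small counts).  Passing tests therefore demonstrate that the pipeline
recovers structure of the planted kind under log-normal noise, not that any
particular real-world ranking is correct.

## Problem sizes

Default study size is 13 conditions × 22 metrics (3 burden, 3 cost, 16
innovation) × 5 years plus 9 stratified series — about 1 550 observations —
matching the pilot's scale.  The rank-recovery experiments use 200
replicates; the engine cross-check uses 1 000 random matrices with up to 8
alternatives and 6 criteria.

## Known limitations

* The overall gap is a *relative* statistic: adding or removing a condition
  can change every score (classic TOPSIS rank-reversal); scores from
  different condition sets are not comparable.
* Monotonicity (raising one condition's raw burden metric never lowers its
  overall gap) is checked empirically under min–max normalisation and
  hierarchical aggregation; it is not a theorem of TOPSIS in general.
* ICD-10 code sets are carried but not validated or mapped across
  terminologies (CCS vs ICD-10).
* Age-standardisation of rates is assumed to have happened upstream.
* Within-domain weights are equal by default; eliciting informed weights
  (e.g. by a Delphi process) is out of scope.
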